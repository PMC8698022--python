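"""Pure-component cubic equation-of-state primitives.

Implements the three classical cubics used for supercritical-CO2 work —
Redlich-Kwong (RK), Soave-Redlich-Kwong (SRK) and Peng-Robinson (PR) — in
the generalized pressure-explicit form

    P = RT/(v - b) - a(T) / [(v + d1*b)(v + d2*b)]

with (d1, d2) = (1, 0) for RK/SRK and (1 + sqrt(2), 1 - sqrt(2)) for PR.
The attraction parameter a(T) already contains the temperature (alpha)
function, so downstream code never needs to know which alpha a given EoS
uses.

Volume roots are obtained analytically (Cardano/trigonometric solution of
the cubic) and polished by Newton iteration on the pressure residual;
only roots larger than the covolume are physical and returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .constants import M_CO2, OMEGA_CO2, PC_CO2, R, TC_CO2, VC_CO2, ZC_CO2
from .errors import DomainError, NumericalError

__all__ = [
    "AlphaKind",
    "EosForm",
    "CriticalSet",
    "PureParams",
    "RK",
    "SRK",
    "PR",
    "CO2_CRIT",
    "get_eos",
    "alpha_function",
    "pure_params",
    "solve_volume",
    "compressibility",
    "co2_density",
]

_SQRT2 = math.sqrt(2.0)


class AlphaKind(str, Enum):
    """Temperature dependence of the attraction parameter."""

    INVERSE_SQRT_T = "inverse_sqrt_T"  # RK: alpha = sqrt(Tc/T)
    SOAVE = "soave"                    # SRK: [1 + s(1 - sqrt(Tr))]^2
    PR = "pr"                          # PR:  [1 + k(1 - sqrt(Tr))]^2


@dataclass(frozen=True)
class EosForm:
    """A cubic EoS: its Omega constants, alpha function and denominator shape."""

    name: str
    omega_a: float
    omega_b: float
    alpha_kind: AlphaKind
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        if self.omega_a <= 0 or self.omega_b <= 0:
            raise DomainError("EoS Omega constants must be positive")


#: Redlich-Kwong.
RK = EosForm("RK", 0.42748, 0.08664, AlphaKind.INVERSE_SQRT_T, 1.0, 0.0)
#: Soave-Redlich-Kwong.
SRK = EosForm("SRK", 0.42748, 0.08664, AlphaKind.SOAVE, 1.0, 0.0)
#: Peng-Robinson (full-precision constants).
PR = EosForm("PR", 0.45724, 0.07780, AlphaKind.PR, 1.0 + _SQRT2, 1.0 - _SQRT2)

_BY_NAME = {"rk": RK, "srk": SRK, "pr": PR}


def get_eos(name: str | EosForm) -> EosForm:
    """Look an EoS up by (case-insensitive) name; pass EosForm through."""
    if isinstance(name, EosForm):
        return name
    try:
        return _BY_NAME[name.lower()]
    except KeyError:
        raise DomainError(f"unknown EoS {name!r}; choose from rk, srk, pr") from None


@dataclass(frozen=True)
class CriticalSet:
    """Critical constants and acentric factor of one component.

    Parameters
    ----------
    tc, pc : float
        Critical temperature (K) and pressure (Pa).
    vc : float, optional
        Critical molar volume, m^3/mol. Required only by the
        Lorentz-Berthelot combining rules.
    zc : float, optional
        Critical compressibility. Required only by Lorentz-Berthelot.
    omega : float
        Acentric factor (enters the Soave/PR alpha functions).
    """

    tc: float
    pc: float
    vc: float | None = None
    zc: float | None = None
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.tc <= 0 or self.pc <= 0:
            raise DomainError("critical temperature and pressure must be positive")
        if self.vc is not None and self.vc <= 0:
            raise DomainError("critical volume must be positive")
        if self.zc is not None and not (0.0 < self.zc < 1.0):
            raise DomainError("critical compressibility must lie in (0, 1)")


#: Carbon dioxide critical set (literature values; overridable by callers).
CO2_CRIT = CriticalSet(tc=TC_CO2, pc=PC_CO2, vc=VC_CO2, zc=ZC_CO2, omega=OMEGA_CO2)


@dataclass(frozen=True)
class PureParams:
    """Attraction a(T) (Pa m^6 mol^-2) and covolume b (m^3 mol^-1) at T (K)."""

    a: float
    b: float
    T: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise DomainError("EoS parameters a, b must be non-negative")


def alpha_function(eos: EosForm, crit: CriticalSet, T: float) -> float:
    """Dimensionless alpha(T) of the given EoS; equals 1 at T = Tc for SRK/PR."""
    tr = T / crit.tc
    if eos.alpha_kind is AlphaKind.INVERSE_SQRT_T:
        return 1.0 / math.sqrt(tr)
    if eos.alpha_kind is AlphaKind.SOAVE:
        s = 0.48 + 1.574 * crit.omega - 0.176 * crit.omega**2
        return (1.0 + s * (1.0 - math.sqrt(tr))) ** 2
    kappa = 0.37464 + 1.54226 * crit.omega - 0.26992 * crit.omega**2
    return (1.0 + kappa * (1.0 - math.sqrt(tr))) ** 2


def pure_params(eos: EosForm, crit: CriticalSet, T: float) -> PureParams:
    """Evaluate a(T) and b for one component.

    a(T) = Omega_a * R^2 Tc^2 / Pc * alpha(T), b = Omega_b * R Tc / Pc.
    For RK the alpha is sqrt(Tc/T), reproducing the familiar
    a/sqrt(T) temperature dependence.
    """
    if T <= 0:
        raise DomainError(f"temperature must be positive, got {T}")
    eos = get_eos(eos)
    a0 = eos.omega_a * R**2 * crit.tc**2 / crit.pc
    b = eos.omega_b * R * crit.tc / crit.pc
    return PureParams(a=a0 * alpha_function(eos, crit, T), b=b, T=T)


def _cubic_real_roots(c2: float, c1: float, c0: float) -> list[float]:
    """Real roots of t^3 + c2 t^2 + c1 t + c0 = 0 (Cardano / trigonometric)."""
    p = c1 - c2 * c2 / 3.0
    q = 2.0 * c2**3 / 27.0 - c2 * c1 / 3.0 + c0
    shift = c2 / 3.0
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    if disc > 0.0:
        s = math.sqrt(disc)
        u = math.copysign(abs(-q / 2.0 + s) ** (1.0 / 3.0), -q / 2.0 + s)
        v = math.copysign(abs(-q / 2.0 - s) ** (1.0 / 3.0), -q / 2.0 - s)
        return [u + v - shift]
    if p == 0.0:  # triple root
        return [-shift]
    m = 2.0 * math.sqrt(-p / 3.0)
    arg = 3.0 * q / (p * m)
    arg = min(1.0, max(-1.0, arg))
    theta = math.acos(arg)
    return [m * math.cos((theta - 2.0 * math.pi * k) / 3.0) - shift for k in range(3)]


def _pressure_residual(eos: EosForm, a: float, b: float, T: float, P: float, v: float) -> float:
    return R * T / (v - b) - a / ((v + eos.delta1 * b) * (v + eos.delta2 * b)) - P


def solve_volume(eos: EosForm, params: PureParams, T: float, P: float) -> list[float]:
    """All physical molar-volume roots at (T, P), sorted ascending.

    Roots are the real solutions v > b of the cubic pressure form; the
    largest is the vapor/supercritical branch used for the fluid phase.
    The analytic roots are polished by Newton iteration on the pressure
    residual to ~1e-12 relative.

    Raises
    ------
    NumericalError
        If no real root exceeds the covolume (diagnostics in ``payload``).
    """
    if T <= 0 or P <= 0:
        raise DomainError(f"T and P must be positive, got T={T}, P={P}")
    eos = get_eos(eos)
    a, b = params.a, params.b
    u = eos.delta1 + eos.delta2
    w = eos.delta1 * eos.delta2
    rtp = R * T / P
    c2 = b * (u - 1.0) - rtp
    c1 = b * b * (w - u) - rtp * u * b + a / P
    c0 = -w * b**3 - rtp * w * b * b - a * b / P

    roots = []
    for v in _cubic_real_roots(c2, c1, c0):
        if v <= b * (1.0 + 1e-13) or v <= 0.0:
            continue
        # Newton polish on the pressure residual
        for _ in range(50):
            f = _pressure_residual(eos, a, b, T, P, v)
            if abs(f) <= 1e-12 * P:
                break
            df = (-R * T / (v - b) ** 2
                  + a * (2.0 * v + u * b) / ((v + eos.delta1 * b) * (v + eos.delta2 * b)) ** 2)
            step = f / df
            v_new = v - step
            if v_new <= b or not math.isfinite(v_new):
                break
            v = v_new
        roots.append(v)

    roots.sort()
    # collapse near-duplicate roots from the analytic stage
    out: list[float] = []
    for v in roots:
        if not out or abs(v - out[-1]) > 1e-9 * max(v, out[-1]):
            out.append(v)
    if not out:
        raise NumericalError(
            "no volume root above the covolume",
            payload={"eos": eos.name, "a": a, "b": b, "T": T, "P": P},
        )
    return out


def compressibility(eos: EosForm, params: PureParams, T: float, P: float) -> float:
    """Fluid-branch compressibility factor Z = P v / (R T)."""
    v = solve_volume(eos, params, T, P)[-1]
    return P * v / (R * T)


def co2_density(T: float, P: float, eos: EosForm = PR, crit: CriticalSet = CO2_CRIT) -> float:
    """Mass density of pure CO2, kg/m^3, from the fluid-branch volume root."""
    params = pure_params(eos, crit, T)
    v = solve_volume(eos, params, T, P)[-1]
    return M_CO2 / v
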
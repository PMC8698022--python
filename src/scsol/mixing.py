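"""Binary mixing rules and the solute fugacity coefficient in the fluid phase.

Two routes are provided:

* the **classical** route — quadratic van der Waals mixing with either a
  direct geometric-mean cross term or Lorentz-Berthelot combining of the
  critical constants, and the closed-form fugacity-coefficient expression
  of the chosen cubic EoS evaluated at the mixture fluid root;

* the **Schmitt-Reid infinite-dilution** route — a modified Peng-Robinson
  treatment in which every term of order y2 is dropped, the binary
  interaction parameter is excluded (a12 = sqrt(a1*a2)), and the solute's
  attraction and covolume (a2, b2) are temperature-independent adjustable
  parameters.  This avoids estimating critical properties of large, fragile
  solutes altogether; only pure-CO2 properties enter the state calculation.

The classical expression at y2 -> 0 with k12 = 0 and the PR form reduces
exactly to the Schmitt-Reid expression; tests assert this reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import R
from .errors import DomainError
from .eos import (
    PR,
    CriticalSet,
    EosForm,
    PureParams,
    get_eos,
    pure_params,
    solve_volume,
)

__all__ = [
    "MixingRule",
    "SchmittReidParams",
    "CrossParams",
    "cross_params_lb",
    "cross_critical_set",
    "mix_vdw",
    "phi2_classical",
    "phi2_schmitt_reid",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class MixingRule:
    """Mixing-rule selection: combining style plus binary interaction parameter.

    ``van_der_waals`` combines attraction terms directly,
    a12 = sqrt(a11*a22)*(1 - k12); ``lorentz_berthelot`` combines the
    *critical constants* first (Tc, Vc, Zc averages with k12 correcting
    the geometric-mean Tc) and evaluates the cross attraction from the
    resulting pseudo-component.
    """

    kind: str = "van_der_waals"
    k12: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("van_der_waals", "lorentz_berthelot"):
            raise DomainError(f"unknown mixing rule kind {self.kind!r}")
        if not abs(self.k12) < 1.0:
            raise DomainError("|k12| must be < 1")


@dataclass(frozen=True)
class SchmittReidParams:
    """Temperature-independent solute parameters of the infinite-dilution route.

    a2 is the solute attraction parameter (Pa m^6 mol^-2) and b2 its
    covolume (m^3 mol^-1); both are regressed from solubility data, never
    computed from critical properties.
    """

    a2: float
    b2: float

    def __post_init__(self) -> None:
        if self.a2 <= 0 or self.b2 <= 0:
            raise DomainError("Schmitt-Reid parameters a2, b2 must be positive")


@dataclass(frozen=True)
class CrossParams:
    """Lorentz-Berthelot cross pseudo-critical constants and RK-form attraction."""

    tc: float
    pc: float
    vc: float
    zc: float
    a: float  # 0.42748 R^2 Tc^2.5 / Pc of the cross pseudo-component


def _require_lb_fields(crit: CriticalSet) -> None:
    if crit.vc is None or crit.zc is None:
        raise DomainError("Lorentz-Berthelot combining needs vc and zc for both components")


def cross_params_lb(crit1: CriticalSet, crit2: CriticalSet, k12: float) -> CrossParams:
    """Lorentz-Berthelot combining of two critical sets.

    Tc12 = (1 - k12) sqrt(Tc1 Tc2); Vc12 = ((Vc1^(1/3) + Vc2^(1/3))/2)^3;
    Zc12 = (Zc1 + Zc2)/2; Pc12 = Zc12 R Tc12 / Vc12; and the RK-convention
    cross attraction a12 = 0.42748 R^2 Tc12^2.5 / Pc12.
    """
    _require_lb_fields(crit1)
    _require_lb_fields(crit2)
    tc = (1.0 - k12) * math.sqrt(crit1.tc * crit2.tc)
    vc = ((crit1.vc ** (1.0 / 3.0) + crit2.vc ** (1.0 / 3.0)) / 2.0) ** 3
    zc = (crit1.zc + crit2.zc) / 2.0
    pc = zc * R * tc / vc
    a = 0.42748 * R**2 * tc**2.5 / pc if tc > 0 else 0.0
    return CrossParams(tc=tc, pc=pc, vc=vc, zc=zc, a=a)


def cross_critical_set(crit1: CriticalSet, crit2: CriticalSet, k12: float) -> CriticalSet:
    """The Lorentz-Berthelot pseudo-component as a CriticalSet.

    The acentric factor is arithmetically averaged so the Soave/PR alpha
    functions remain applicable to the cross term.
    """
    cp = cross_params_lb(crit1, crit2, k12)
    if cp.tc <= 0:
        raise DomainError("degenerate cross critical temperature (k12 = 1?)")
    return CriticalSet(tc=cp.tc, pc=cp.pc, vc=cp.vc, zc=cp.zc,
                       omega=(crit1.omega + crit2.omega) / 2.0)


def mix_vdw(y2: float, a11: float, a12: float, a22: float,
            b1: float, b2: float) -> tuple[float, float]:
    """Quadratic van der Waals mixing for a binary at solute fraction y2."""
    if not 0.0 <= y2 <= 1.0:
        raise DomainError(f"mole fraction y2 must lie in [0, 1], got {y2}")
    y1 = 1.0 - y2
    a_mix = y1 * y1 * a11 + 2.0 * y1 * y2 * a12 + y2 * y2 * a22
    b_mix = y1 * b1 + y2 * b2
    return a_mix, b_mix


def _cross_a(eos: EosForm, rule: MixingRule, crit1: CriticalSet, crit2: CriticalSet,
             a11: float, a22: float, T: float) -> float:
    if rule.kind == "van_der_waals":
        return math.sqrt(a11 * a22) * (1.0 - rule.k12)
    # Lorentz-Berthelot: evaluate the EoS's own a(T) on the cross
    # pseudo-component. For RK this is exactly 0.42748 R^2 Tc12^2.5/(Pc12 sqrt(T)).
    return pure_params(eos, cross_critical_set(crit1, crit2, rule.k12), T).a


def ln_phi_component(eos: EosForm, a_mix: float, b_mix: float, bk: float,
                     sum_ya_k: float, T: float, P: float) -> float:
    """Closed-form ln(phi_k) for the generalized cubic with quadratic mixing.

    ``sum_ya_k`` is sum_i y_i a_ik. The ideal-gas degenerate case
    (a_mix = b_mix = 0) returns 0.
    """
    if a_mix == 0.0 and b_mix == 0.0:
        return 0.0
    eos = get_eos(eos)
    v = solve_volume(eos, PureParams(a=a_mix, b=b_mix, T=T), T, P)[-1]
    z = P * v / (R * T)
    big_a = a_mix * P / (R * T) ** 2
    big_b = b_mix * P / (R * T)
    out = (bk / b_mix) * (z - 1.0) - math.log(z - big_b)
    if a_mix > 0.0:
        out -= (big_a / (big_b * (eos.delta1 - eos.delta2))
                * (2.0 * sum_ya_k / a_mix - bk / b_mix)
                * math.log((z + eos.delta1 * big_b) / (z + eos.delta2 * big_b)))
    return out


def phi2_classical(eos: EosForm, rule: MixingRule, crit1: CriticalSet,
                   crit2: CriticalSet, T: float, P: float, y2: float) -> float:
    """Solute fugacity coefficient in the binary fluid at composition y2.

    Evaluates the closed-form expression of the chosen cubic EoS at the
    mixture fluid root (largest volume root of the mixed parameters).
    crit1 is the solvent (CO2), crit2 the solute.
    """
    eos = get_eos(eos)
    p1 = pure_params(eos, crit1, T)
    p2 = pure_params(eos, crit2, T)
    a12 = _cross_a(eos, rule, crit1, crit2, p1.a, p2.a, T)
    a_mix, b_mix = mix_vdw(y2, p1.a, a12, p2.a, p1.b, p2.b)
    sum_ya_2 = (1.0 - y2) * a12 + y2 * p2.a
    return math.exp(ln_phi_component(eos, a_mix, b_mix, p2.b, sum_ya_2, T, P))


def phi2_schmitt_reid(T: float, P: float, pure1: PureParams,
                      sr: SchmittReidParams) -> float:
    """Infinite-dilution solute fugacity coefficient, modified PR form.

    ln(phi2) = (b2/b1)(Z - 1) - ln[P(V - b1)/RT]
               - a1/(sqrt(8) R T b1) * (2 sqrt(a2/a1) - b2/b1)
                 * ln[(V + (1+sqrt2) b1)/(V + (1-sqrt2) b1)]

    with V, Z the pure-CO2 PR fluid-root volume and compressibility at
    (T, P). No binary interaction parameter enters (a12 = sqrt(a1 a2)).
    """
    a1, b1 = pure1.a, pure1.b
    v = solve_volume(PR, pure1, T, P)[-1]
    if v <= (_SQRT2 - 1.0) * b1:
        raise DomainError("volume root below the PR logarithm singularity")
    z = P * v / (R * T)
    ln_phi = (sr.b2 / b1) * (z - 1.0) - math.log(P * (v - b1) / (R * T))
    ln_phi -= (a1 / (math.sqrt(8.0) * R * T * b1)
               * (2.0 * math.sqrt(sr.a2 / a1) - sr.b2 / b1)
               * math.log((v + (1.0 + _SQRT2) * b1) / (v + (1.0 - _SQRT2) * b1)))
    return math.exp(ln_phi)
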
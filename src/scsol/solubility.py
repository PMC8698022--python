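"""The compressed-gas model for solid solubility in a supercritical fluid.

Equating the pure-solid fugacity (sublimation pressure times a Poynting
pressure correction) with the solute fugacity in the fluid phase gives

    y2 = (P2sub / P) * E(T, P) / phi2

where E is the Poynting factor and phi2 the solute fugacity coefficient in
the fluid. Because P2sub of drug-like solids is many orders of magnitude
below the operating pressure, the simplified Poynting convention
E = exp(v2s P / RT) (with the solid-phase fugacity coefficient taken as 1)
is the working default; the full form exp[v2s (P - P2sub)/RT] is available
behind a flag for sensitivity work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import R
from .errors import DomainError, NumericalError
from .eos import CO2_CRIT, PR, CriticalSet, EosForm, get_eos, pure_params
from .mixing import MixingRule, SchmittReidParams, phi2_classical, phi2_schmitt_reid

__all__ = ["SoluteProperties", "poynting_factor", "solubility"]


@dataclass(frozen=True)
class SoluteProperties:
    """Solid-solute properties needed by the solubility model.

    Parameters
    ----------
    name : str
        Label used in reports.
    v2s : float
        Solid molar volume, m^3/mol (e.g. 2.261e-4 for penicillin G,
        2.432e-4 for penicillin V from the experimental determination;
        the older group-contribution estimate 2.13e-4 is sometimes used
        for penicillin V).
    crit : CriticalSet, optional
        Pseudo-critical constants and acentric factor; required by the
        classical EoS route only.
    sr : SchmittReidParams, optional
        Adjustable (a2, b2); required by the Schmitt-Reid route only.
    """

    name: str
    v2s: float
    crit: CriticalSet | None = None
    sr: SchmittReidParams | None = None

    def __post_init__(self) -> None:
        if self.v2s <= 0:
            raise DomainError("solid molar volume v2s must be positive")


def poynting_factor(v2s: float, T: float, P: float, p_sub: float = 0.0,
                    full: bool = False) -> float:
    """Pressure correction to the solid-phase fugacity.

    ``full`` gives exp[v2s (P - p_sub)/RT]; otherwise the simplified
    convention exp[v2s P / RT] is used (the two are indistinguishable
    whenever p_sub << P, which holds for every system of interest here).
    """
    if P <= 0:
        raise DomainError("pressure must be positive")
    if p_sub < 0:
        raise DomainError("sublimation pressure must be non-negative")
    dp = (P - p_sub) if full else P
    return math.exp(v2s * dp / (R * T))


def solubility(T: float, P: float, solute: SoluteProperties, p_sub: float,
               route: str = "schmitt_reid", eos: EosForm | str = PR,
               rule: MixingRule | None = None,
               crit_solvent: CriticalSet = CO2_CRIT,
               full_poynting: bool = False) -> float:
    """Equilibrium solute mole fraction y2 at (T, P).

    Parameters
    ----------
    route : {"schmitt_reid", "classical"}
        Schmitt-Reid: phi2 is composition-independent, so y2 follows by
        direct evaluation. Classical: phi2 depends on y2, so the defining
        relation is solved by fixed-point iteration
        y2 <- (p_sub/P) E / phi2(y2), seeded at the phi2 = 1 estimate and
        converged to 1e-10 relative (at most 200 iterations).
    p_sub : float
        Sublimation pressure at T, Pa. This is the dominant driver of the
        predicted solubility.

    Raises
    ------
    NumericalError
        On fixed-point divergence or a result outside (0, 1); the payload
        carries the last iterate.
    """
    if p_sub <= 0:
        raise DomainError("p_sub must be positive")
    poy = poynting_factor(solute.v2s, T, P, p_sub=p_sub, full=full_poynting)
    base = (p_sub / P) * poy

    if route == "schmitt_reid":
        if solute.sr is None:
            raise DomainError("Schmitt-Reid route needs solute.sr parameters")
        phi2 = phi2_schmitt_reid(T, P, pure_params(PR, crit_solvent, T), solute.sr)
        y2 = base / phi2
        if not 0.0 < y2 < 1.0:
            raise NumericalError("solubility outside (0, 1)",
                                 payload={"y2": y2, "phi2": phi2, "T": T, "P": P})
        return y2

    if route != "classical":
        raise DomainError(f"unknown route {route!r}")
    if solute.crit is None:
        raise DomainError("classical route needs solute.crit")
    eos = get_eos(eos)
    rule = rule if rule is not None else MixingRule()

    y2 = min(base, 0.5)
    for _ in range(200):
        phi2 = phi2_classical(eos, rule, crit_solvent, solute.crit, T, P, y2)
        y2_new = base / phi2
        if not 0.0 < y2_new < 1.0 or not math.isfinite(y2_new):
            raise NumericalError("classical fixed point left (0, 1)",
                                 payload={"last": y2, "next": y2_new, "T": T, "P": P})
        if abs(y2_new - y2) <= 1e-10 * y2_new:
            return y2_new
        y2 = y2_new
    raise NumericalError("classical fixed point did not converge",
                         payload={"last": y2, "T": T, "P": P})
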
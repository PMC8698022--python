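"""Density-based semi-empirical solubility correlations and the
sublimation-pressure estimation pipeline.

Two single-line collapses are used:

* Mendez-Santiago-Teja (MST): T ln(y2 P) = A' + B' rho + C' T. Fitted
  with P in Pa, the intercept C' is directly the Clausius-Clapeyron
  intercept AS of ln P2sub(Pa) = AS - dHs/(R T).
* Bartle: ln(y2 P / P_ref) = a + b/T + c (rho - rho_ref) with P_ref = 1 bar
  and rho_ref = 700 kg/m^3; the slope b encodes the sublimation enthalpy,
  dHs = -b R.

The three-step estimation procedure — consistency check on the MST
collapse, MST fit for AS, Bartle fit for BS = dHs — produces a
SublimationModel from solubility data alone, avoiding both boiling-point
methods (useless for thermolabile drugs) and treating P2sub as a free
regression parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BAR, R
from .datasets import SolubilityDataset
from .errors import InputError
from .sublimation import SublimationModel

__all__ = [
    "MstFit",
    "BartleFit",
    "ConsistencyReport",
    "NewPsubResult",
    "aard",
    "mst_fit",
    "bartle_fit",
    "consistency_check",
    "estimate_new_psub",
]

#: Bartle reference pressure, Pa (1 bar), and reference density, kg/m^3.
BARTLE_P_REF = BAR
BARTLE_RHO_REF = 700.0

_DENSITY_SCALE = {
    # multiplicative factor applied to the stored kg/m^3 column
    "kg_m3": 1.0,
    "mol_cm3": 1.0 / 44.01e3,  # kg/m^3 -> mol/cm^3 for CO2
}


@dataclass(frozen=True)
class MstFit:
    """MST coefficients: A' (K), B' (K per density unit), C' (dimensionless)."""

    A: float
    B: float
    C: float
    aard: float
    density_unit: str = "kg_m3"


@dataclass(frozen=True)
class BartleFit:
    """Bartle coefficients (a, b, c) plus the implied sublimation enthalpy."""

    a: float
    b: float
    c: float
    aard: float
    dHs: float  # J/mol, equals -b*R by definition

    def __post_init__(self) -> None:
        if not math.isclose(self.dHs, -self.b * R, rel_tol=1e-12, abs_tol=1e-9):
            raise InputError("BartleFit.dHs must equal -b*R")


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-point outlier flags and the pooled-line R^2 of the MST collapse."""

    flags: np.ndarray = field(repr=False)
    z_scores: np.ndarray = field(repr=False)
    r_squared: float

    @property
    def n_flagged(self) -> int:
        return int(np.sum(self.flags))


@dataclass(frozen=True)
class NewPsubResult:
    """Output of the three-step sublimation-pressure estimation."""

    model: SublimationModel
    mst: MstFit
    bartle: BartleFit
    consistency: ConsistencyReport
    n_used: int
    n_dropped: int


def aard(y_exp, y_calc) -> float:
    """Average absolute relative deviation, percent: 100/N sum|e - c|/e."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_calc = np.asarray(y_calc, dtype=float)
    if y_exp.shape != y_calc.shape or y_exp.size == 0:
        raise InputError("y_exp and y_calc must be equal-length, non-empty")
    if np.any(y_exp <= 0):
        raise InputError("experimental values must be positive")
    return float(100.0 * np.mean(np.abs(y_exp - y_calc) / y_exp))


def _design_data(data: SolubilityDataset, density_unit: str = "kg_m3"):
    if not data.has_density or data.frame["density_kg_m3"].isna().any():
        raise InputError("dataset needs a complete density column "
                         "(use with_densities or density_source='eos')")
    try:
        scale = _DENSITY_SCALE[density_unit]
    except KeyError:
        raise InputError(f"unknown density unit {density_unit!r}") from None
    T = data.frame["temperature_K"].to_numpy(float)
    P = data.frame["pressure_Pa"].to_numpy(float)
    y2 = data.frame["y2"].to_numpy(float)
    rho = data.frame["density_kg_m3"].to_numpy(float) * scale
    return T, P, y2, rho


def _lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise InputError("rank-deficient design: data do not span the model")
    return beta


def mst_fit(data: SolubilityDataset, density_unit: str = "kg_m3") -> MstFit:
    """Pooled least-squares MST fit T ln(y2 P[Pa]) = A' + B' rho + C' T.

    All isotherms enter one regression — the model is a single-line
    collapse by construction. The AARD is computed on back-transformed
    solubilities.
    """
    T, P, y2, rho = _design_data(data, density_unit)
    if len(T) < 3:
        raise InputError("MST fit needs at least 3 points")
    X = np.column_stack([np.ones_like(T), rho, T])
    y = T * np.log(y2 * P)
    A, B, C = _lstsq(X, y)
    y2_pred = np.exp((A + B * rho + C * T) / T) / P
    return MstFit(A=float(A), B=float(B), C=float(C),
                  aard=aard(y2, y2_pred), density_unit=density_unit)


def bartle_fit(data: SolubilityDataset) -> BartleFit:
    """Pooled least-squares Bartle fit ln(y2 P / 1 bar) = a + b/T + c (rho - 700).

    Density in kg/m^3; the slope b (K) gives the sublimation enthalpy
    dHs = -b R exactly.
    """
    T, P, y2, rho = _design_data(data, "kg_m3")
    if len(T) < 3:
        raise InputError("Bartle fit needs at least 3 points")
    X = np.column_stack([np.ones_like(T), 1.0 / T, rho - BARTLE_RHO_REF])
    y = np.log(y2 * P / BARTLE_P_REF)
    a, b, c = _lstsq(X, y)
    y2_pred = np.exp(a + b / T + c * (rho - BARTLE_RHO_REF)) * BARTLE_P_REF / P
    return BartleFit(a=float(a), b=float(b), c=float(c),
                     aard=aard(y2, y2_pred), dHs=float(-b * R))


def consistency_check(data: SolubilityDataset, fit: MstFit | None = None,
                      z_threshold: float = 2.0) -> ConsistencyReport:
    """Flag points that fall off the MST single-line collapse.

    The collapse coordinate s = T ln(y2 P) - C' T is plotted against
    density; a point is inconsistent when its standardized residual about
    the pooled line s = A' + B' rho exceeds ``z_threshold`` in absolute
    value. Returns the flags, the z-scores and the pooled-line R^2.
    """
    if fit is None:
        fit = mst_fit(data)
    T, P, y2, rho = _design_data(data, fit.density_unit)
    s = T * np.log(y2 * P) - fit.C * T
    resid = s - (fit.A + fit.B * rho)
    scale = float(np.std(resid))
    # an exactly collinear collapse leaves only rounding noise; do not
    # standardize by a scale that is numerically zero
    if scale <= 1e-9 * max(1.0, float(np.mean(np.abs(s)))):
        z = np.zeros_like(resid)
    else:
        z = resid / scale
    flags = np.abs(z) > z_threshold
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return ConsistencyReport(flags=flags, z_scores=z, r_squared=r2)


def estimate_new_psub(data: SolubilityDataset, z_threshold: float = 2.0,
                      density_unit: str = "kg_m3") -> NewPsubResult:
    """Three-step sublimation-pressure estimation from solubility data.

    1. consistency check on the pooled MST collapse; flagged points are
       dropped from the correlation step (they remain valid data for any
       later solubility calculation);
    2. MST refit on the retained points -> AS = C' (P in Pa);
    3. Bartle fit on the retained points -> BS = dHs = -b R.
    """
    report = consistency_check(data, mst_fit(data, density_unit), z_threshold)
    keep = ~report.flags
    if not keep.any():
        raise InputError("all points flagged inconsistent; nothing to fit")
    clean = SolubilityDataset(data.frame[keep].copy())
    mst = mst_fit(clean, density_unit)
    bartle = bartle_fit(clean)
    model = SublimationModel(AS=mst.C, BS=bartle.dHs)
    return NewPsubResult(model=model, mst=mst, bartle=bartle,
                         consistency=report, n_used=int(keep.sum()),
                         n_dropped=int((~keep).sum()))
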
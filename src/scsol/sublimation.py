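"""Clausius-Clapeyron representation of sublimation pressure.

ln P2sub(Pa) = AS - BS/(R T), with AS a dimensionless intercept and BS the
sublimation enthalpy in J/mol. Fitting per-temperature sublimation
pressures to this form extracts the enthalpy from the slope; the
discrepancy metric quantifies how far two independently regressed
sublimation pressures disagree at the same temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .constants import R
from .errors import DomainError, InputError

__all__ = [
    "SublimationModel",
    "clausius_pressure",
    "fit_clausius",
    "pressure_discrepancy",
]


@dataclass(frozen=True)
class SublimationModel:
    """Clausius-Clapeyron pair: intercept AS (ln Pa) and enthalpy BS (J/mol)."""

    AS: float
    BS: float

    def pressure(self, T: float) -> float:
        return clausius_pressure(self, T)


def clausius_pressure(model: SublimationModel, T: float) -> float:
    """Sublimation pressure exp(AS - BS/(R T)), Pa."""
    if T <= 0:
        raise DomainError("temperature must be positive")
    return math.exp(model.AS - model.BS / (R * T))


def fit_clausius(points: Iterable[tuple[float, float]]) -> SublimationModel:
    """Ordinary least squares of ln(p_sub) against 1/T.

    The slope s maps to BS = -s*R and the intercept to AS. At least two
    points with distinct temperatures are required; the fit round-trips
    exactly on noiseless data from any SublimationModel.
    """
    pts = list(points)
    if len(pts) < 2:
        raise InputError("need at least two (T, p_sub) points")
    T = np.array([p[0] for p in pts], dtype=float)
    p = np.array([p[1] for p in pts], dtype=float)
    if np.any(T <= 0) or np.any(p <= 0):
        raise InputError("temperatures and pressures must be positive")
    if len(np.unique(T)) < 2:
        raise InputError("temperatures must not all coincide")
    x = 1.0 / T
    slope, intercept = np.polyfit(x, np.log(p), 1)
    return SublimationModel(AS=float(intercept), BS=float(-slope * R))


def pressure_discrepancy(p_ref: float, p_other: float) -> float:
    """Percent disagreement 100*|p_ref - p_other|/p_ref.

    The first argument is the reference (denominator); it is
    scale-invariant, so any common pressure unit may be used.
    """
    if p_ref <= 0:
        raise DomainError("reference pressure must be positive")
    return 100.0 * abs(p_ref - p_other) / p_ref
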
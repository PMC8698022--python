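"""AARD-objective regression of EoS parameters against solubility isotherms.

Three regression modes mirror the literature treatments of the two
penicillin-CO2 systems:

* ``classical`` with free per-isotherm sublimation pressures — one global
  binary interaction parameter k12 plus one P2sub per isotherm (the
  "second adjustable parameter" treatment used with RK/SRK and
  Lorentz-Berthelot combining);
* ``classical`` with fixed sublimation pressures — k12 alone, with P2sub
  supplied from a Clausius-Clapeyron model or a table;
* ``schmitt_reid`` — temperature-independent solute parameters (a2, b2)
  of the modified-PR infinite-dilution route, with P2sub always supplied.

The objective is the global AARD (percent) of the forward compressed-gas
model over all points. It is non-convex, so a seeded multi-start
Nelder-Mead simplex is used: log-space for strictly positive parameters
(P2sub, a2, b2), linear space for k12 in (-1, 1). State points where the
forward model fails contribute a large penalty (1e3 percent) instead of
aborting, letting the simplex escape unphysical regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .datasets import SolubilityDataset
from .empirical import aard
from .eos import CO2_CRIT, PR, CriticalSet, EosForm, get_eos, pure_params
from .errors import InputError, ScsolError
from .mixing import MixingRule, SchmittReidParams, phi2_schmitt_reid
from .solubility import SoluteProperties, poynting_factor, solubility
from .sublimation import SublimationModel

__all__ = ["FitResult", "fit_classical", "fit_schmitt_reid"]

_FAIL_PENALTY = 1.0e3  # percent contributed by a failed forward point


@dataclass
class FitResult:
    """Regression outcome: parameters, fit quality, and bookkeeping."""

    mode: str
    params: dict[str, float] = field(default_factory=dict)
    aard_global: float = math.nan
    aard_by_T: dict[float, float] = field(default_factory=dict)
    n_points: int = 0
    converged: bool = False
    objective_evals: int = 0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "params": self.params,
            "aard_global_percent": self.aard_global,
            "aard_by_T_percent": {f"{t:g}": v for t, v in self.aard_by_T.items()},
            "n_points": self.n_points,
            "converged": self.converged,
            "objective_evals": self.objective_evals,
        }


def _psub_lookup(psub, temperatures) -> dict[float, float]:
    """Normalize a SublimationModel / mapping into per-isotherm pressures (Pa)."""
    if isinstance(psub, SublimationModel):
        return {t: psub.pressure(t) for t in temperatures}
    table = {}
    for t in temperatures:
        match = [v for tt, v in psub.items() if math.isclose(tt, t, abs_tol=1e-6)]
        if not match:
            raise InputError(f"no sublimation pressure supplied for isotherm T={t}")
        table[t] = float(match[0])
    if any(v <= 0 for v in table.values()):
        raise InputError("sublimation pressures must be positive")
    return table


def _per_isotherm_aard(frame, y_calc: np.ndarray) -> dict[float, float]:
    out: dict[float, float] = {}
    T = frame["temperature_K"].to_numpy(float)
    y_exp = frame["y2"].to_numpy(float)
    for t in sorted(np.unique(T)):
        m = T == t
        out[float(t)] = aard(y_exp[m], y_calc[m])
    return out


class _Objective:
    """Wraps a forward model; counts evaluations and penalizes failures."""

    def __init__(self, forward):
        self.forward = forward
        self.evals = 0

    def __call__(self, x: np.ndarray) -> float:
        self.evals += 1
        y_exp, y_calc = self.forward(x)
        terms = np.where(np.isfinite(y_calc),
                         100.0 * np.abs(y_exp - y_calc) / y_exp,
                         _FAIL_PENALTY)
        return float(np.mean(terms))


def _multistart(objective: _Objective, starts: list[np.ndarray],
                max_evals: int = 5000) -> tuple[np.ndarray, float, bool]:
    best_x, best_f, best_ok = None, math.inf, False
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10,
                                "maxfev": max_evals, "adaptive": True})
        if res.fun < best_f:
            best_x, best_f, best_ok = res.x, float(res.fun), bool(res.success)
    return best_x, best_f, best_ok


def _sr_initial_a2(data: SolubilityDataset, solute: SoluteProperties,
                   psub_by_T: dict[float, float], b2: float) -> float:
    """Invert the infinite-dilution expression for a2 at the data centroid.

    For each point the fugacity coefficient the data demand is
    phi2 = (psub/P) E / y2; averaging the implied 2*sqrt(a2/a1) over
    points gives a well-scaled starting attraction parameter.
    """
    from .constants import R as _R
    from .eos import solve_volume

    vals = []
    for _, row in data.frame.iterrows():
        T, P, y2 = row["temperature_K"], row["pressure_Pa"], row["y2"]
        p1 = pure_params(PR, CO2_CRIT, T)
        v = solve_volume(PR, p1, T, P)[-1]
        z = P * v / (_R * T)
        ln_phi_needed = math.log(psub_by_T[float(T)] / P
                                 * poynting_factor(solute.v2s, T, P) / y2)
        coef = (p1.a / (math.sqrt(8.0) * _R * T * p1.b)
                * math.log((v + (1 + math.sqrt(2)) * p1.b)
                           / (v + (1 - math.sqrt(2)) * p1.b)))
        k1 = (b2 / p1.b) * (z - 1.0) - math.log(P * (v - p1.b) / (_R * T))
        root_ratio = (b2 / p1.b + (k1 - ln_phi_needed) / coef) / 2.0
        if root_ratio > 0:
            vals.append(p1.a * root_ratio**2)
    if not vals:
        return 1.0
    return float(np.exp(np.mean(np.log(vals))))


def fit_schmitt_reid(data: SolubilityDataset, solute: SoluteProperties,
                     psub, seed: int = 0, n_starts: int = 8,
                     max_evals: int = 5000) -> FitResult:
    """Regress the temperature-independent (a2, b2) of the modified-PR route.

    ``psub`` (a SublimationModel or a {T: Pa} mapping) supplies the
    sublimation pressure of every isotherm; this mode never fits it.
    """
    if len(data) < 2:
        raise InputError("need at least 2 points to fit (a2, b2)")
    temperatures = data.temperatures
    psub_by_T = _psub_lookup(psub, temperatures)
    frame = data.frame
    T = frame["temperature_K"].to_numpy(float)
    P = frame["pressure_Pa"].to_numpy(float)
    y_exp = frame["y2"].to_numpy(float)
    psub_row = np.array([psub_by_T[float(t)] for t in T])
    poy = np.array([poynting_factor(solute.v2s, t, p) for t, p in zip(T, P)])
    pure1 = {t: pure_params(PR, CO2_CRIT, t) for t in temperatures}

    def forward(x: np.ndarray):
        a2, b2 = math.exp(x[0]), math.exp(x[1])
        y_calc = np.full_like(y_exp, np.nan)
        try:
            sr = SchmittReidParams(a2=a2, b2=b2)
        except ScsolError:
            return y_exp, y_calc
        for i in range(len(y_exp)):
            try:
                phi2 = phi2_schmitt_reid(T[i], P[i], pure1[float(T[i])], sr)
                y_calc[i] = psub_row[i] / P[i] * poy[i] / phi2
            except ScsolError:
                pass
        return y_exp, y_calc

    rng = np.random.default_rng(seed)
    b2_0 = solute.v2s
    a2_0 = _sr_initial_a2(data, solute, psub_by_T, b2_0)
    x_center = np.array([math.log(a2_0), math.log(b2_0)])
    starts = [x_center] + [x_center + rng.normal(0.0, 0.7, size=2)
                           for _ in range(n_starts - 1)]

    objective = _Objective(forward)
    x_best, _, ok = _multistart(objective, starts, max_evals)
    a2, b2 = math.exp(x_best[0]), math.exp(x_best[1])

    _, y_final = forward(x_best)
    clean = bool(np.all(np.isfinite(y_final)))
    result = FitResult(mode="schmitt_reid",
                       params={"a2": a2, "b2": b2},
                       aard_global=aard(y_exp, y_final) if clean else math.inf,
                       aard_by_T=_per_isotherm_aard(frame, y_final) if clean else {},
                       n_points=len(data), converged=ok and clean,
                       objective_evals=objective.evals)
    return result


def fit_classical(data: SolubilityDataset, solute: SoluteProperties,
                  eos: EosForm | str, rule_kind: str = "lorentz_berthelot",
                  psub_mode: str = "per_isotherm_free", psub=None,
                  crit_solvent: CriticalSet = CO2_CRIT,
                  seed: int = 0, n_starts: int = 8,
                  max_evals: int = 5000) -> FitResult:
    """Regress k12 (and optionally per-isotherm P2sub) for a classical cubic EoS.

    ``psub_mode="per_isotherm_free"`` fits one global k12 plus one
    sublimation pressure per isotherm; ``psub_mode="fixed"`` fits k12
    alone with P2sub supplied through ``psub``.
    """
    eos = get_eos(eos)
    if solute.crit is None:
        raise InputError("classical fitting needs solute pseudo-critical constants")
    temperatures = data.temperatures
    n_iso = len(temperatures)
    free_psub = psub_mode == "per_isotherm_free"
    if psub_mode not in ("per_isotherm_free", "fixed"):
        raise InputError(f"unknown psub_mode {psub_mode!r}")
    n_params = 1 + (n_iso if free_psub else 0)
    if len(data) < n_params + 1:
        raise InputError(
            f"under-determined fit: {len(data)} points for {n_params} parameters")
    if not free_psub:
        if psub is None:
            raise InputError("psub_mode='fixed' requires psub")
        fixed_psub = _psub_lookup(psub, temperatures)

    frame = data.frame
    T = frame["temperature_K"].to_numpy(float)
    P = frame["pressure_Pa"].to_numpy(float)
    y_exp = frame["y2"].to_numpy(float)

    def forward(x: np.ndarray):
        k12 = float(x[0])
        y_calc = np.full_like(y_exp, np.nan)
        if not abs(k12) < 1.0:
            return y_exp, y_calc
        rule = MixingRule(kind=rule_kind, k12=k12)
        if free_psub:
            psub_by_T = {t: math.exp(x[1 + j]) for j, t in enumerate(temperatures)}
        else:
            psub_by_T = fixed_psub
        for i in range(len(y_exp)):
            try:
                y_calc[i] = solubility(T[i], P[i], solute,
                                       p_sub=psub_by_T[float(T[i])],
                                       route="classical", eos=eos, rule=rule,
                                       crit_solvent=crit_solvent)
            except ScsolError:
                pass
        return y_exp, y_calc

    # seed the sublimation pressures from the phi2(k12=0) implied values
    def implied_psub(k12: float) -> dict[float, float]:
        rule = MixingRule(kind=rule_kind, k12=k12)
        out = {}
        for t in temperatures:
            iso = data.isotherm(t).frame
            vals = []
            for _, row in iso.iterrows():
                try:
                    from .mixing import phi2_classical
                    phi2 = phi2_classical(eos, rule, crit_solvent, solute.crit,
                                          row["temperature_K"], row["pressure_Pa"],
                                          row["y2"])
                    vals.append(row["y2"] * row["pressure_Pa"] * phi2
                                / poynting_factor(solute.v2s, row["temperature_K"],
                                                  row["pressure_Pa"]))
                except ScsolError:
                    pass
            out[t] = float(np.exp(np.mean(np.log(vals)))) if vals else 1e-6
        return out

    rng = np.random.default_rng(seed)
    psub0 = implied_psub(0.0) if free_psub else None
    starts = []
    for j in range(n_starts):
        k0 = 0.0 if j == 0 else float(rng.uniform(-0.3, 0.3))
        if free_psub:
            jitter = np.zeros(n_iso) if j == 0 else rng.normal(0.0, 1.0, size=n_iso)
            x0 = np.concatenate([[k0],
                                 np.array([math.log(psub0[t]) for t in temperatures])
                                 + jitter])
        else:
            x0 = np.array([k0])
        starts.append(np.asarray(x0, dtype=float))

    objective = _Objective(forward)
    x_best, _, ok = _multistart(objective, starts, max_evals)

    params = {"k12": float(x_best[0])}
    if free_psub:
        for j, t in enumerate(temperatures):
            params[f"psub_Pa_{t:g}K"] = math.exp(x_best[1 + j])

    _, y_final = forward(x_best)
    clean = bool(np.all(np.isfinite(y_final)))
    mode = f"classical_{eos.name.lower()}_{'free' if free_psub else 'fixed'}_psub"
    return FitResult(mode=mode, params=params,
                     aard_global=aard(y_exp, y_final) if clean else math.inf,
                     aard_by_T=_per_isotherm_aard(frame, y_final) if clean else {},
                     n_points=len(data), converged=ok and clean,
                     objective_evals=objective.evals)
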
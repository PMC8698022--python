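"""Forward-simulated solubility datasets with known ground truth.

The original penicillin solubility measurements (18 points for
penicillin G over 313.15-333.15 K, 24 points for penicillin V over
314.85-334.85 K) were never published as tables, so every pipeline stage
here is exercised on data generated by the package's own forward model:
a known sublimation-pressure model and known solute parameters produce
noiseless solubilities on a (T, P) grid, optionally multiplied by
mean-one lognormal noise and by targeted outlier factors. The generating
truth is returned alongside the data so recovery tests can close the loop.

Noise is multiplicative because solubilities span decades and the fit
metric (AARD) is relative; it is strictly positive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import BAR
from .datasets import SolubilityDataset
from .eos import PR, CriticalSet, EosForm
from .errors import InputError, ScsolError
from .mixing import MixingRule, SchmittReidParams
from .solubility import SoluteProperties, solubility
from .sublimation import SublimationModel

__all__ = ["ForwardTruth", "GeneratorConfig", "generate", "penicillin_fixture"]


@dataclass(frozen=True)
class ForwardTruth:
    """The generating forward model: route, solute and sublimation pressures."""

    route: str  # "schmitt_reid" | "classical"
    solute: SoluteProperties
    sublimation: SublimationModel | None = None
    psub_by_T: dict[float, float] | None = None
    eos: EosForm = PR
    rule: MixingRule | None = None

    def psub(self, T: float) -> float:
        if self.sublimation is not None:
            return self.sublimation.pressure(T)
        if self.psub_by_T is None:
            raise InputError("truth carries neither a SublimationModel nor a table")
        for t, p in self.psub_by_T.items():
            if abs(t - T) < 1e-6:
                return p
        raise InputError(f"no truth sublimation pressure at T={T}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Grid, truth, noise level and seed of one synthetic dataset."""

    temperatures: tuple[float, ...]
    pressures_bar: tuple[float, ...]
    truth: ForwardTruth
    noise_cv: float = 0.08
    seed: int = 0
    outliers: tuple[tuple[float, float, float], ...] = ()  # (T, P_bar, multiplier)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InputError("noise_cv must be non-negative")

    @property
    def n_points(self) -> int:
        return len(self.temperatures) * len(self.pressures_bar)


def generate(config: GeneratorConfig) -> tuple[SolubilityDataset, ForwardTruth]:
    """Simulate a solubility dataset from the configured forward model.

    Returns the dataset (densities filled from the PR EoS) and the truth
    record. Noise with coefficient of variation ``noise_cv`` is lognormal
    with unit mean; outlier multipliers are applied after the noise.
    """
    truth = config.truth
    rows_T, rows_P, rows_y = [], [], []
    for T in config.temperatures:
        p_sub = truth.psub(T)
        for P_bar in config.pressures_bar:
            P = P_bar * BAR
            try:
                y2 = solubility(T, P, truth.solute, p_sub=p_sub, route=truth.route,
                                eos=truth.eos, rule=truth.rule)
            except ScsolError as exc:
                raise InputError(
                    f"forward model failed at T={T} K, P={P_bar} bar: {exc}") from exc
            rows_T.append(T)
            rows_P.append(P)
            rows_y.append(y2)

    y = np.array(rows_y)
    if config.noise_cv > 0:
        rng = np.random.default_rng(config.seed)
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        y = y * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=y.size)

    for T_o, P_o, mult in config.outliers:
        hit = [i for i in range(len(rows_T))
               if abs(rows_T[i] - T_o) < 1e-6 and abs(rows_P[i] / BAR - P_o) < 1e-6]
        if not hit:
            raise InputError(f"outlier target ({T_o} K, {P_o} bar) not on the grid")
        for i in hit:
            y[i] = y[i] * mult

    ds = SolubilityDataset.from_arrays(np.array(rows_T), np.array(rows_P), y)
    return ds.with_densities(eos=PR), truth


# --- penicillin-like study fixtures -------------------------------------

#: Solid molar volumes, m^3/mol (experimental determinations).
V2S_PENG = 2.261e-4
V2S_PENV = 2.432e-4
#: Older group-contribution estimate for penicillin V, m^3/mol.
V2S_PENV_GCM = 2.13e-4

#: Clausius-Clapeyron sublimation models (ln Pa intercept, J/mol enthalpy)
#: from the density-correlation estimation route.
SUBLIMATION_PENG = SublimationModel(AS=26.2, BS=85_300.0)
SUBLIMATION_PENV = SublimationModel(AS=12.8, BS=41_900.0)

#: Fixture truth (a2, b2) for the infinite-dilution route. The covolumes
#: sit at the solid-molar-volume scale (~2e-4 m^3/mol); the attraction
#: parameters are set so the simulated solubilities land in the
#: 1e-6..1e-4 mole-fraction window typical of drug solids in CO2.
SR_TRUTH_PENG = SchmittReidParams(a2=13.0, b2=1.98e-4)
SR_TRUTH_PENV = SchmittReidParams(a2=12.0, b2=2.72e-4)

#: Standard constructed-outlier setting for consistency-check exercises:
#: the two lowest-density states (the ones the original analysis removed)
#: perturbed by a factor of five, one upward and one downward.
PENG_OUTLIERS = ((323.15, 100.0, 5.0), (333.15, 100.0, 0.2))


def penicillin_fixture(which: str, noise_cv: float = 0.08, seed: int = 0,
                       outliers: tuple[tuple[float, float, float], ...] = ()
                       ) -> GeneratorConfig:
    """Study-shaped generator configs for the two penicillin-CO2 systems.

    ``penG``: 3 isotherms at 313.15/323.15/333.15 K x 6 pressures
    (N = 18); ``penV``: 3 isotherms at 314.85/324.85/334.85 K x 8
    pressures (N = 24). Both use the Schmitt-Reid forward route with the
    Clausius-Clapeyron sublimation models above.
    """
    if which == "penG":
        solute = SoluteProperties(name="penicillin G", v2s=V2S_PENG, sr=SR_TRUTH_PENG)
        return GeneratorConfig(
            temperatures=(313.15, 323.15, 333.15),
            pressures_bar=(100.0, 150.0, 200.0, 250.0, 300.0, 350.0),
            truth=ForwardTruth(route="schmitt_reid", solute=solute,
                               sublimation=SUBLIMATION_PENG),
            noise_cv=noise_cv, seed=seed, outliers=outliers)
    if which == "penV":
        solute = SoluteProperties(name="penicillin V", v2s=V2S_PENV, sr=SR_TRUTH_PENV)
        return GeneratorConfig(
            temperatures=(314.85, 324.85, 334.85),
            pressures_bar=tuple(np.linspace(100.0, 350.0, 8).round(1)),
            truth=ForwardTruth(route="schmitt_reid", solute=solute,
                               sublimation=SUBLIMATION_PENV),
            noise_cv=noise_cv, seed=seed, outliers=outliers)
    raise InputError(f"unknown fixture {which!r}; choose 'penG' or 'penV'")


def classical_fixture(seed: int = 0, noise_cv: float = 0.0,
                      eos: EosForm | str = "rk", k12: float = 0.10) -> GeneratorConfig:
    """A classical-route fixture with Lorentz-Berthelot combining.

    Uses synthetic pseudo-critical solute constants of penicillin-G-like
    magnitude (Tc = 700 K, Vc = 6e-4 m^3/mol, Zc = 0.25) and per-isotherm
    sublimation pressures from the penicillin G Clausius-Clapeyron model.
    """
    from .eos import get_eos

    crit2 = CriticalSet(tc=700.0, pc=0.25 * 8.314462618 * 700.0 / 6.0e-4,
                        vc=6.0e-4, zc=0.25, omega=0.8)
    solute = SoluteProperties(name="synthetic penicillin-like solute",
                              v2s=V2S_PENG, crit=crit2)
    temps = (313.15, 323.15, 333.15)
    psub = {t: SUBLIMATION_PENG.pressure(t) for t in temps}
    return GeneratorConfig(
        temperatures=temps,
        pressures_bar=(100.0, 150.0, 200.0, 250.0, 300.0, 350.0),
        truth=ForwardTruth(route="classical", solute=solute, psub_by_T=psub,
                           eos=get_eos(eos),
                           rule=MixingRule(kind="lorentz_berthelot", k12=k12)),
        noise_cv=noise_cv, seed=seed)


def with_outliers(config: GeneratorConfig,
                  outliers: tuple[tuple[float, float, float], ...]) -> GeneratorConfig:
    """Copy of ``config`` with outlier multipliers attached."""
    return replace(config, outliers=outliers)
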
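"""Published reference values for the two penicillin-CO2 systems.

These are regression results reported in the literature — per-isotherm
sublimation pressures obtained by treating P2sub as an adjustable
parameter (Gordillo et al. with RK/SRK for penicillin G; Ko et al. with
PR and a modified Clausius-Clapeyron estimate for penicillin V), and the
MST/Bartle correlation coefficients of the density-based estimation
route. They serve as *inputs* to the consistency checks exposed by the
``tables`` CLI command: discrepancy percentages between rival sublimation
pressures, Clausius-Clapeyron enthalpies implied by the per-isotherm
values, and the enthalpy identity dHs = -b R of the Bartle slope.
"""

from __future__ import annotations

from .constants import BAR, R
from .sublimation import fit_clausius, pressure_discrepancy

__all__ = [
    "PENG_PSUB_RK_BAR",
    "PENG_PSUB_SRK_BAR",
    "PENV_PSUB_CLAUSIUS_BAR",
    "PENV_PSUB_PR_BAR",
    "MST_COEFFS",
    "BARTLE_COEFFS",
    "penG_discrepancies",
    "penV_discrepancies",
    "penG_enthalpies_kj",
    "bartle_enthalpies_kj",
    "reference_checks",
]

#: Penicillin G per-isotherm sublimation pressures (bar) regressed with
#: the RK and SRK cubics (Lorentz-Berthelot combining), by temperature (K).
PENG_PSUB_RK_BAR = {313.15: 3.55e-12, 323.15: 2.24e-11, 333.15: 1.44e-10}
PENG_PSUB_SRK_BAR = {313.15: 2.82e-12, 323.15: 4.57e-11, 333.15: 3.09e-9}

#: Penicillin V per-isotherm sublimation pressures (bar): modified
#: Clausius-Clapeyron estimate vs PR regression.
PENV_PSUB_CLAUSIUS_BAR = {314.85: 5.53e-10, 324.85: 1.54e-9, 334.85: 3.83e-9}
PENV_PSUB_PR_BAR = {314.85: 1.15e-10, 324.85: 9.10e-9, 334.85: 3.93e-7}

#: MST coefficients (A' in K, B' in K per density unit, C' dimensionless).
MST_COEFFS = {
    "penG": {"A": -11_475.4, "B": 165_852.2, "C": 26.2},
    "penV": {"A": -5_495.9, "B": 73_223.7, "C": 12.8},
}

#: Bartle coefficients (a dimensionless, b in K, c in m^3/kg).
BARTLE_COEFFS = {
    "penG": {"a": 25.1, "b": -10_260.3, "c": 1.2e-2},
    "penV": {"a": 12.6, "b": -5_049.7, "c": 5.05e-3},
}


def penG_discrepancies() -> dict[float, float]:
    """Percent disagreement of the RK-regressed P2sub from the SRK one.

    The SRK value is the reference (denominator), per-temperature.
    """
    return {t: pressure_discrepancy(PENG_PSUB_SRK_BAR[t], PENG_PSUB_RK_BAR[t])
            for t in sorted(PENG_PSUB_SRK_BAR)}


def penV_discrepancies() -> dict[float, float]:
    """Percent disagreement of the Clausius-estimated P2sub from the PR one."""
    return {t: pressure_discrepancy(PENV_PSUB_PR_BAR[t], PENV_PSUB_CLAUSIUS_BAR[t])
            for t in sorted(PENV_PSUB_PR_BAR)}


def penG_enthalpies_kj() -> dict[str, float]:
    """Sublimation enthalpies (kJ/mol) implied by the per-isotherm P2sub values.

    Clausius-Clapeyron OLS over the three temperatures, per EoS column.
    The very large values are one symptom that adjustable-parameter
    sublimation pressures are unreliable.
    """
    out = {}
    for name, table in (("rk", PENG_PSUB_RK_BAR), ("srk", PENG_PSUB_SRK_BAR)):
        model = fit_clausius([(t, p * BAR) for t, p in table.items()])
        out[name] = model.BS / 1e3
    return out


def bartle_enthalpies_kj() -> dict[str, float]:
    """dHs = -b R from the Bartle slopes, kJ/mol."""
    return {name: -coeffs["b"] * R / 1e3 for name, coeffs in BARTLE_COEFFS.items()}


def reference_checks() -> dict:
    """All published-value consistency checks in one structure."""
    return {
        "penG_psub_discrepancy_percent": penG_discrepancies(),
        "penV_psub_discrepancy_percent": penV_discrepancies(),
        "penG_clausius_enthalpy_kJ_mol": penG_enthalpies_kj(),
        "bartle_enthalpy_kJ_mol": bartle_enthalpies_kj(),
    }
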
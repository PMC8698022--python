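"""Tidy container and CSV I/O for isothermal solubility measurements.

A dataset is a table of (temperature, pressure, solute mole fraction)
records grouped into isotherms, optionally carrying the CO2 density at
each state point. On disk the format is a plain CSV with header columns
``temperature_K``, ``pressure_bar``, ``y2`` and optionally
``density_kg_m3``; internally pressures are SI (Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import BAR
from .errors import InputError
from .eos import PR, EosForm, co2_density

__all__ = ["SolubilityDataset", "read_dataset", "write_dataset"]

_COLUMNS = ["temperature_K", "pressure_Pa", "y2", "density_kg_m3"]


@dataclass
class SolubilityDataset:
    """Solubility records with columns temperature_K, pressure_Pa, y2[, density_kg_m3]."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS[:3] if c not in self.frame.columns]
        if missing:
            raise InputError(f"dataset missing columns: {missing}")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, T: np.ndarray, P_pa: np.ndarray, y2: np.ndarray,
                    density: np.ndarray | None = None) -> "SolubilityDataset":
        frame = pd.DataFrame({"temperature_K": np.asarray(T, float),
                              "pressure_Pa": np.asarray(P_pa, float),
                              "y2": np.asarray(y2, float)})
        if density is not None:
            frame["density_kg_m3"] = np.asarray(density, float)
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def temperatures(self) -> list[float]:
        """Distinct isotherm temperatures, ascending."""
        return sorted(self.frame["temperature_K"].unique().tolist())

    @property
    def has_density(self) -> bool:
        return "density_kg_m3" in self.frame.columns

    def isotherm(self, T: float, atol: float = 1e-9) -> "SolubilityDataset":
        mask = np.isclose(self.frame["temperature_K"], T, atol=atol)
        return SolubilityDataset(self.frame[mask].copy())

    def with_densities(self, eos: EosForm = PR) -> "SolubilityDataset":
        """Return a copy with CO2 densities filled from the EoS where absent."""
        frame = self.frame.copy()
        if "density_kg_m3" not in frame.columns:
            frame["density_kg_m3"] = np.nan
        need = frame["density_kg_m3"].isna()
        frame.loc[need, "density_kg_m3"] = [
            co2_density(t, p, eos=eos)
            for t, p in zip(frame.loc[need, "temperature_K"], frame.loc[need, "pressure_Pa"])
        ]
        return SolubilityDataset(frame)


def read_dataset(path: str | Path, density_source: str = "column",
                 eos: EosForm = PR) -> SolubilityDataset:
    """Read a solubility CSV (temperature_K, pressure_bar, y2[, density_kg_m3]).

    Validates every row; a malformed cell or out-of-range solubility is
    reported with its (1-based, header-exclusive) row number. With
    ``density_source="eos"`` missing densities are computed from the
    chosen cubic EoS on load.
    """
    try:
        raw = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise InputError(f"cannot read {path}: {exc}") from exc
    required = ["temperature_K", "pressure_bar", "y2"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")

    for col in required + (["density_kg_m3"] if "density_kg_m3" in raw.columns else []):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & ~raw[col].isna() | raw[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise InputError(f"{path}: non-numeric or empty value in {col!r} at row {row}")
        raw[col] = vals

    for col, lo in (("temperature_K", 0.0), ("pressure_bar", 0.0)):
        bad = raw[col] <= lo
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise InputError(f"{path}: non-positive {col!r} at row {row}")
    bad = (raw["y2"] <= 0.0) | (raw["y2"] >= 1.0)
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise InputError(f"{path}: y2 outside (0, 1) at row {row}")

    frame = pd.DataFrame({"temperature_K": raw["temperature_K"],
                          "pressure_Pa": raw["pressure_bar"] * BAR,
                          "y2": raw["y2"]})
    if "density_kg_m3" in raw.columns:
        frame["density_kg_m3"] = raw["density_kg_m3"]
    ds = SolubilityDataset(frame)
    if density_source == "eos":
        ds = ds.with_densities(eos=eos)
    elif density_source != "column":
        raise InputError(f"unknown density_source {density_source!r}")
    return ds


def write_dataset(ds: SolubilityDataset, path: str | Path) -> None:
    """Write the standard CSV dialect (pressures in bar, '.' decimals)."""
    out = pd.DataFrame({"temperature_K": ds.frame["temperature_K"],
                        "pressure_bar": ds.frame["pressure_Pa"] / BAR,
                        "y2": ds.frame["y2"]})
    if ds.has_density:
        out["density_kg_m3"] = ds.frame["density_kg_m3"]
    out.to_csv(path, index=False, lineterminator="\n")
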
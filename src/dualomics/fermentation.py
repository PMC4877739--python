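"""Growth and fermentation balance metrics.

Carbon recovery is the fraction of consumed substrate carbon recovered in
the measured end-products; the O/R ratio is the oxidized-product
equivalents divided by the reduced-product equivalents, both computed from
molar concentration changes.  O/R values follow the classical
fermentation-balance convention (CO2 +2, formate +1, H2 -1, ethanol -2,
acetate and lactate 0) and are user-overridable via a table file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RedoxTable:
    """Per-compound O/R values and carbon atoms per mole."""

    or_values: Mapping[str, float]
    carbons: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(self.or_values) - set(self.carbons)
        if missing:
            raise ValueError(f"compounds without carbon counts: {sorted(missing)}")

    def require(self, compound: str) -> None:
        if compound not in self.or_values:
            raise KeyError(f"compound {compound!r} not in redox table")

    @classmethod
    def default(cls) -> "RedoxTable":
        return cls(
            or_values={
                "CO2": 2.0,
                "formate": 1.0,
                "H2": -1.0,
                "ethanol": -2.0,
                "acetate": 0.0,
                "lactate": 0.0,
                "glucose": 0.0,
                "cellobiose": 0.0,
                "xylose": 0.0,
            },
            carbons={
                "CO2": 1,
                "formate": 1,
                "H2": 0,
                "ethanol": 2,
                "acetate": 2,
                "lactate": 3,
                "glucose": 6,
                "cellobiose": 12,
                "xylose": 5,
            },
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RedoxTable":
        table = pd.read_csv(path, sep="\t")
        for col in ("compound", "or_value", "carbons"):
            if col not in table.columns:
                raise ValueError(f"{path}: missing redox table column {col!r}")
        return cls(
            or_values=dict(zip(table["compound"], table["or_value"].astype(float))),
            carbons=dict(zip(table["compound"], table["carbons"].astype(int))),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "compound": list(self.or_values),
                "or_value": [self.or_values[c] for c in self.or_values],
                "carbons": [self.carbons[c] for c in self.or_values],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class FermentationSeries:
    """A fermentation time course.

    ``data`` holds a strictly increasing ``time`` column (hours), a
    biomass proxy column, a substrate concentration column (mM) and one
    column per end-product (mM).
    """

    data: pd.DataFrame
    substrate: str
    biomass_col: str = "od600"
    products: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "time" not in self.data.columns:
            raise ValueError("series needs a 'time' column")
        times = self.data["time"].to_numpy(float)
        if (np.diff(times) <= 0).any():
            raise ValueError("time must be strictly increasing")
        if not self.products:
            reserved = {"time", self.biomass_col, self.substrate}
            self.products = tuple(c for c in self.data.columns if c not in reserved)
        for col in (self.biomass_col, self.substrate, *self.products):
            if col not in self.data.columns:
                raise ValueError(f"series lacks column {col!r}")
            if (self.data[col].to_numpy(float) < -1e-12).any():
                raise ValueError(f"negative concentrations in column {col!r}")

    @classmethod
    def from_csv(
        cls, path: str | Path, substrate: str, biomass_col: str = "od600"
    ) -> "FermentationSeries":
        return cls(pd.read_csv(path), substrate=substrate, biomass_col=biomass_col)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6f")

    def deltas(self) -> tuple[float, dict[str, float]]:
        """(substrate consumed, per-product concentration increase) over the course."""
        first, last = self.data.iloc[0], self.data.iloc[-1]
        consumed = float(first[self.substrate] - last[self.substrate])
        produced = {p: float(last[p] - first[p]) for p in self.products}
        return consumed, produced


def doubling_time(
    series: FermentationSeries, window: tuple[float, float]
) -> tuple[float, float]:
    """Exponential-phase specific growth rate and hours per generation.

    Fits ln(biomass) against time by least squares over the points inside
    ``window`` (inclusive); doubling time = ln(2) / slope.
    """
    lo, hi = window
    mask = (series.data["time"] >= lo) & (series.data["time"] <= hi)
    times = series.data.loc[mask, "time"].to_numpy(float)
    biomass = series.data.loc[mask, series.biomass_col].to_numpy(float)
    if len(times) < 3:
        raise ValueError("need at least 3 points in the growth window")
    if (biomass <= 0).any():
        raise ValueError("non-positive biomass in the growth window")
    fit = stats.linregress(times, np.log(biomass))
    mu = float(fit.slope)
    if mu <= 0:
        raise ValueError("no exponential growth in the window (slope <= 0)")
    return mu, math.log(2) / mu


def carbon_recovery(
    substrate_consumed_mm: float,
    substrate_carbons: int,
    products_mm: Mapping[str, float],
    table: RedoxTable | None = None,
) -> float:
    """Fraction of consumed substrate carbon found in the end-products."""
    table = table or RedoxTable.default()
    if substrate_consumed_mm <= 0:
        raise ValueError("substrate consumption must be positive")
    if substrate_carbons <= 0:
        raise ValueError("substrate carbon count must be positive")
    recovered = 0.0
    for compound, mm in products_mm.items():
        table.require(compound)
        recovered += mm * table.carbons[compound]
    return recovered / (substrate_consumed_mm * substrate_carbons)


def or_ratio(
    products_mm: Mapping[str, float], table: RedoxTable | None = None
) -> float:
    """Oxidized over reduced product equivalents (both sides positive)."""
    table = table or RedoxTable.default()
    oxidized = 0.0
    reduced = 0.0
    for compound, mm in products_mm.items():
        table.require(compound)
        value = table.or_values[compound]
        if value > 0:
            oxidized += mm * value
        elif value < 0:
            reduced += mm * value
    if reduced == 0:
        raise ValueError("O/R undefined: no reduced products")
    return oxidized / abs(reduced)


def balance_summary(
    series: FermentationSeries,
    window: tuple[float, float] | None = None,
    table: RedoxTable | None = None,
) -> dict[str, float]:
    """Doubling time (if a window is given) plus carbon recovery and O/R ratio."""
    table = table or RedoxTable.default()
    table.require(series.substrate)
    consumed, produced = series.deltas()
    summary: dict[str, float] = {
        "substrate_consumed_mm": consumed,
        "carbon_recovery": carbon_recovery(
            consumed, table.carbons[series.substrate], produced, table
        ),
        "or_ratio": or_ratio(produced, table),
    }
    if window is not None:
        mu, td = doubling_time(series, window)
        summary["growth_rate_per_h"] = mu
        summary["doubling_time_h"] = td
    return summary
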
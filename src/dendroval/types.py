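"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Column schema of a climate table (long format, one row per observation).
CLIMATE_COLUMNS = ["site_id", "product", "year", "month", "precip_mm"]


@dataclass
class RingSeries:
    """Annual ring widths (mm) of one core, over consecutive calendar years."""

    site_id: str
    series_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or len(self.widths) == 0:
            raise ValueError("widths must be a non-empty 1-d array")
        if np.any(~np.isfinite(self.widths)) or np.any(self.widths <= 0):
            raise ValueError(
                f"series {self.series_id}: widths must be finite and > 0"
            )

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class Chronology:
    """Standardized site-level growth index with per-year sample depth."""

    site_id: str
    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.index = np.asarray(self.index, dtype=float)
        self.sample_depth = np.asarray(self.sample_depth, dtype=int)
        if not (len(self.years) == len(self.index) == len(self.sample_depth)):
            raise ValueError("years, index and sample_depth must align")
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise ValueError("chronology years must be consecutive")
        if np.any(self.sample_depth < 1):
            raise ValueError("index defined only where sample_depth >= 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.index, index=pd.Index(self.years, name="year"))


class ClimateTable:
    """Monthly precipitation keyed by (site_id, product, year, month).

    Thin wrapper over a long-format :class:`pandas.DataFrame` with schema
    ``site_id, product, year, month, precip_mm``; validates key uniqueness,
    month range and non-negative precipitation on construction.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"climate table missing columns: {missing}")
        df = df.loc[:, CLIMATE_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["month"] = df["month"].astype(int)
        df["precip_mm"] = df["precip_mm"].astype(float)
        if validate:
            if df["month"].min() < 1 or df["month"].max() > 12:
                raise ValueError("month must lie in 1..12")
            if (df["precip_mm"] < 0).any():
                bad = df.loc[df["precip_mm"] < 0].iloc[0]
                raise ValueError(
                    "negative precipitation at "
                    f"({bad.site_id}, {bad['product']}, {bad.year}, {bad.month})"
                )
            dup = df.duplicated(["site_id", "product", "year", "month"])
            if dup.any():
                bad = df.loc[dup].iloc[0]
                raise ValueError(
                    "duplicate key "
                    f"({bad.site_id}, {bad['product']}, {bad.year}, {bad.month})"
                )
        self.df = df.reset_index(drop=True)

    @property
    def products(self) -> list[str]:
        return sorted(self.df["product"].unique())

    @property
    def sites(self) -> list[str]:
        return sorted(self.df["site_id"].unique())

    def monthly_series(self, site_id: str, product: str) -> pd.Series:
        """Series indexed by (year, month) for one site and product."""
        sub = self.df[
            (self.df["site_id"] == site_id) & (self.df["product"] == product)
        ]
        return sub.set_index(["year", "month"])["precip_mm"].sort_index()

    def sorted_frame(self) -> pd.DataFrame:
        return (
            self.df.sort_values(["site_id", "product", "year", "month"])
            .reset_index(drop=True)
        )

    def equals(self, other: "ClimateTable") -> bool:
        return self.sorted_frame().equals(other.sorted_frame())

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class LaggedDesign:
    """One site x product regression problem.

    ``predictors`` holds the 8 monthly precipitation values (mm) of each
    growth year's lagged window, column j = lag month j oldest -> newest;
    ``response`` is the standardized growth or greenness value.
    """

    site_id: str
    product_id: str
    years: np.ndarray
    response: np.ndarray
    predictors: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.response = np.asarray(self.response, dtype=float)
        self.predictors = np.asarray(self.predictors, dtype=float)
        if self.predictors.shape != (len(self.years), 8):
            raise ValueError("predictors must be |years| x 8")
        if len(self.response) != len(self.years):
            raise ValueError("response must align with years")
        if np.any(~np.isfinite(self.response)) or np.any(
            ~np.isfinite(self.predictors)
        ):
            raise ValueError("design contains missing cells")

    @property
    def n_obs(self) -> int:
        return len(self.years)

    def restrict(self, years) -> "LaggedDesign":
        """Design restricted to the given growth years (order preserved)."""
        keep = np.isin(self.years, np.asarray(list(years), dtype=int))
        return LaggedDesign(
            self.site_id,
            self.product_id,
            self.years[keep],
            self.response[keep],
            self.predictors[keep],
        )


@dataclass
class SyntheticStudy:
    """A complete synthetic validation study with known planted structure."""

    truth: ClimateTable
    products: ClimateTable
    ring_series: Mapping[str, list[RingSeries]]
    evi_series: Mapping[str, pd.Series]
    region_of: Mapping[str, str]
    hemisphere_of: Mapping[str, str]
    signal_of: Mapping[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site in list(self.ring_series) + list(self.evi_series):
            if site not in self.region_of:
                raise ValueError(f"site {site} has no region label")
            if site not in self.hemisphere_of:
                raise ValueError(f"site {site} has no hemisphere label")
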
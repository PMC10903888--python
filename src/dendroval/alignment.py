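"""Growth-year to climate-window alignment and design assembly.

Each growth year is paired with the 8 consecutive months ending at the close
of the growing season: August of the growth year in the northern hemisphere
(January..August), February in the southern hemisphere (July of the previous
calendar year through February of the growth year; the growth year is
labelled by the calendar year containing the season's end, the standard
Schulman convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ClimateTable, LaggedDesign

N_LAG_MONTHS = 8
END_MONTH = {"N": 8, "S": 2}


@dataclass(frozen=True)
class SeasonConvention:
    """Hemisphere-specific growing-season window convention."""

    hemisphere: str
    n_lag_months: int = N_LAG_MONTHS

    def __post_init__(self) -> None:
        if self.hemisphere not in END_MONTH:
            raise ValueError("hemisphere must be 'N' or 'S'")
        if self.n_lag_months != N_LAG_MONTHS:
            raise ValueError("the lagged window is fixed at 8 months")

    @property
    def end_month(self) -> int:
        return END_MONTH[self.hemisphere]


def window_months(growth_year: int, convention) -> list[tuple[int, int]]:
    """The 8 (calendar_year, month) pairs of one growth year's climate
    window, oldest first, ending at (and including) the season end month."""
    if isinstance(convention, str):
        convention = SeasonConvention(convention)
    end = convention.end_month
    out = []
    for back in range(N_LAG_MONTHS - 1, -1, -1):
        m = end - back
        y = growth_year
        while m < 1:
            m += 12
            y -= 1
        out.append((y, m))
    return out


def growth_years(calendar_years: Sequence[int], convention) -> np.ndarray:
    """Growth years whose full window lies within the given calendar years."""
    years = np.asarray(calendar_years, dtype=int)
    if isinstance(convention, str):
        convention = SeasonConvention(convention)
    lo, hi = years.min(), years.max()
    out = []
    for gy in range(lo, hi + 1):
        months = window_months(gy, convention)
        if months[0][0] >= lo and months[-1][0] <= hi:
            out.append(gy)
    return np.asarray(out, dtype=int)


def build_design(
    growth: pd.Series,
    climate: ClimateTable | pd.Series,
    product_id: str,
    convention,
) -> LaggedDesign:
    """Assemble the lagged regression design for one site and product.

    ``growth`` is an annual series indexed by growth year (site id taken
    from ``growth.name`` unless the climate argument carries one).  Rows are
    emitted only for growth years whose response is non-missing and whose
    full 8-month window exists in the climate table.  An empty design (zero
    usable rows) is returned as such, not raised.
    """
    if isinstance(convention, str):
        convention = SeasonConvention(convention)
    if len(growth) == 0:
        raise ValueError("growth series is empty")
    site_id = str(growth.name) if growth.name is not None else ""
    if isinstance(climate, ClimateTable):
        monthly = climate.monthly_series(site_id, product_id)
    else:
        monthly = climate
    lookup = monthly.to_dict()
    years, rows, resp = [], [], []
    for gy, value in growth.sort_index().items():
        if pd.isna(value):
            continue
        vals = [lookup.get(key, np.nan) for key in window_months(int(gy), convention)]
        if np.any(np.isnan(vals)):
            continue
        years.append(int(gy))
        rows.append(vals)
        resp.append(float(value))
    resp = np.asarray(resp)
    if len(resp) > 1 and np.std(resp) > 0:
        resp = (resp - resp.mean()) / resp.std()
    return LaggedDesign(
        site_id,
        product_id,
        np.asarray(years, dtype=int),
        resp,
        np.asarray(rows, dtype=float).reshape(len(years), N_LAG_MONTHS),
    )


def pairwise_complete(
    designs: Mapping[str, LaggedDesign]
) -> dict[str, LaggedDesign]:
    """Restrict every product's design to the intersection of usable growth
    years, so all products are scored on identical site-years.  An empty
    intersection yields empty designs (flagged by their zero length)."""
    if len(designs) < 2:
        raise ValueError("pairwise completion needs at least 2 products")
    year_sets = [set(d.years.tolist()) for d in designs.values()]
    common = sorted(set.intersection(*year_sets))
    return {pid: d.restrict(common) for pid, d in designs.items()}
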
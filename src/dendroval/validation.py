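"""Regression skill scoring: un-adjusted R² per site x product, over the
full shared period and in moving windows.

The score is deliberately simple: ordinary least squares of the annual
growth/greenness response on an intercept plus the 8 monthly precipitation
predictors, reporting the un-adjusted coefficient of determination
R² = 1 - SSE/SST.  With every modelling choice held fixed across products,
differences in R² isolate differences in climate-product quality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.linalg

from .config import ValidationConfig
from .types import LaggedDesign

log = logging.getLogger(__name__)

N_PREDICTORS = 8
#: Minimum rows for any reported fit: 8 predictors + intercept + 1.
MIN_FIT_ROWS = N_PREDICTORS + 2
#: Relative pivot tolerance for dropping collinear predictor columns.
RANK_TOL = 1e-10


@dataclass
class FitResult:
    site_id: str
    product_id: str
    scope: str  # "full" or the window midpoint year as a string
    r_squared: float  # NaN when undefined (constant response)
    n_obs: int


def _ols_r_squared(X: np.ndarray, y: np.ndarray) -> float:
    """Un-adjusted R² of y on an intercept plus the columns of X.

    Collinear columns are eliminated by pivoted QR (relative tolerance
    ``RANK_TOL``) and the reduced fit is reported.  Returns NaN when the
    response is constant (SST = 0).
    """
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst <= 0:
        return np.nan
    Xc = X - X.mean(axis=0)
    q, r, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > RANK_TOL * max(diag[0], 1e-300)))
    if rank < Xc.shape[1]:
        log.warning("dropping %d collinear predictor column(s)",
                    Xc.shape[1] - rank)
    if rank == 0:
        return 0.0
    qr_ = q[:, :rank]
    resid = yc - qr_ @ (qr_.T @ yc)
    sse = float(resid @ resid)
    return max(0.0, min(1.0, 1.0 - sse / sst))


def r_squared(design: LaggedDesign) -> FitResult:
    """Full-design OLS fit of one site x product problem."""
    if design.n_obs < MIN_FIT_ROWS:
        raise ValueError(
            f"need at least {MIN_FIT_ROWS} rows, got {design.n_obs}"
        )
    r2 = _ols_r_squared(design.predictors, design.response)
    return FitResult(design.site_id, design.product_id, "full", r2,
                     design.n_obs)


def full_period_validation(
    site_designs: Mapping[str, Mapping[str, LaggedDesign]],
    config: ValidationConfig | None = None,
) -> pd.DataFrame:
    """One full-period FitResult per site x product.

    ``site_designs`` maps site -> product -> pairwise-complete design.  A
    site that fails the minimum-observation cut, or whose fit is undefined
    for any product, is excluded for ALL products so the comparison stays
    balanced.
    """
    config = config or ValidationConfig()
    rows: list[FitResult] = []
    for site in sorted(site_designs):
        designs = site_designs[site]
        _check_balanced(designs)
        n = next(iter(designs.values())).n_obs
        if n < max(config.min_obs_full, MIN_FIT_ROWS):
            continue
        fits = [r_squared(d) for _, d in sorted(designs.items())]
        if any(np.isnan(f.r_squared) for f in fits):
            continue
        rows.extend(fits)
    return _to_frame(rows)


def window_starts(config: ValidationConfig) -> list[int]:
    lo, hi = config.eval_span
    w = config.window_length
    return list(range(lo, hi - w + 2, config.window_step))


def window_midpoint(first_year: int, window_length: int) -> int:
    return first_year + (window_length - 1) // 2


def moving_window_validation(
    site_designs: Mapping[str, Mapping[str, LaggedDesign]],
    config: ValidationConfig | None = None,
) -> pd.DataFrame:
    """Windowed fits reported at window midpoints.

    Windows of ``window_length`` years advance by ``window_step`` within
    ``eval_span``, anchored to calendar years (not to a site's own coverage)
    so midpoints align across sites.  With ``require_complete_window`` a
    window is fitted only where the design holds all of its years; because
    designs are pairwise-complete the same windows are skipped for every
    product of a site.
    """
    config = config or ValidationConfig()
    w = config.window_length
    starts = window_starts(config)
    rows: list[FitResult] = []
    for site in sorted(site_designs):
        designs = site_designs[site]
        _check_balanced(designs)
        any_design = next(iter(designs.values()))
        have = set(any_design.years.tolist())
        for s in starts:
            wyears = range(s, s + w)
            if config.require_complete_window:
                if not all(y in have for y in wyears):
                    continue
                n_in = w
            else:
                n_in = sum(y in have for y in wyears)
                if n_in < MIN_FIT_ROWS:
                    continue
            mid = str(window_midpoint(s, w))
            fits = []
            for _, d in sorted(designs.items()):
                sub = d.restrict(wyears)
                r2 = _ols_r_squared(sub.predictors, sub.response)
                fits.append(FitResult(d.site_id, d.product_id, mid, r2,
                                      sub.n_obs))
            if any(np.isnan(f.r_squared) for f in fits):
                continue  # balance: skip the window for every product
            rows.extend(fits)
    return _to_frame(rows)


def _check_balanced(designs: Mapping[str, LaggedDesign]) -> None:
    year_sets = {tuple(d.years.tolist()) for d in designs.values()}
    if len(year_sets) > 1:
        raise ValueError(
            "designs are not pairwise-complete; run pairwise_complete first"
        )


def _to_frame(rows: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": f.site_id,
                "product_id": f.product_id,
                "window": f.scope,
                "r_squared": f.r_squared,
                "n_obs": f.n_obs,
            }
            for f in rows
        ],
        columns=["site_id", "product_id", "window", "r_squared", "n_obs"],
    )
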
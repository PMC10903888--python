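"""Site chronology construction from raw ring-width series.

The stages mirror standard dendrochronological practice: each core is
detrended by dividing its widths by a fitted growth curve (Friedman's
variable-span "supersmoother"), the detrended index of each core is
pre-whitened by removing a Yule-Walker autoregressive fit, and cores are
averaged year-by-year with Tukey's biweight robust mean.

The smoother, the biweight estimator and the AR order-selection logic are
implemented here directly so their numerical behaviour is fully specified by
this module.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .config import ChronologyConfig, DetrendConfig
from .types import Chronology, RingSeries

log = logging.getLogger(__name__)

#: Friedman's candidate span fractions: tweeter, midrange, woofer.
SPANS = (0.05, 0.2, 0.5)

#: Shortest series the variable-span smoother accepts; shorter series are
#: detrended by their own mean instead.
MIN_SMOOTH_LENGTH = 10

#: Below this many values the biweight mean falls back to the median.
MIN_BIWEIGHT_N = 4


class SeriesTooShortError(ValueError):
    """Series shorter than the smoother minimum; caller should fall back to a
    flat (mean) growth curve."""


# ---------------------------------------------------------------------------
# Friedman supersmoother


def _local_linear(x, y, w, half):
    """Running weighted local-linear smooth with symmetric windows of
    half-width ``half`` points (truncated at the boundaries).

    Returns (fitted, cv_residual) where cv_residual is the leave-one-out
    residual obtained from the hat-diagonal identity of linear smoothers.
    """
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1) + 1  # exclusive

    def seg(values):
        c = np.concatenate(([0.0], np.cumsum(values)))
        return c[hi] - c[lo]

    W = seg(w)
    xbar = seg(w * x) / W
    ybar = seg(w * y) / W
    sxx = seg(w * x * x) - W * xbar**2
    sxy = seg(w * x * y) - W * xbar * ybar
    scale = np.maximum(seg(w * x * x), 1.0)
    ok = sxx > 1e-12 * scale
    slope = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
    fitted = ybar + slope * (x - xbar)
    lever = w / W + np.where(ok, w * (x - xbar) ** 2 / np.where(ok, sxx, 1.0), 0.0)
    denom = np.maximum(1.0 - lever, 1e-10)
    cv_resid = (y - fitted) / denom
    return fitted, cv_resid


def _half_width(span: float, n: int) -> int:
    return max(1, int(span * n + 0.5) // 2)


def supersmooth(
    x: Sequence[float],
    y: Sequence[float],
    config: DetrendConfig | None = None,
) -> np.ndarray:
    """Friedman's variable-span smoother.

    Local-linear fits are computed at three candidate spans (roughly 0.05,
    0.2 and 0.5 of the series length); the span used at each point is the one
    with the smallest smoothed leave-one-out absolute residual, the selected
    spans are themselves smoothed, and the final fit interpolates between the
    candidate-span fits.  ``bass`` > 0 biases the span choice toward the
    largest span.  With a fixed ``span`` fraction a single-span local-linear
    smooth is returned instead.

    Parameters
    ----------
    x, y : 1-d arrays of equal length, ``x`` strictly increasing.
    config : DetrendConfig, optional

    Returns
    -------
    ndarray of fitted values at ``x``.
    """
    config = config or DetrendConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < MIN_SMOOTH_LENGTH:
        raise SeriesTooShortError(
            f"series of length {n} < {MIN_SMOOTH_LENGTH}; detrend by the "
            "series mean instead"
        )
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if config.case_weights is not None:
        w = np.asarray(config.case_weights, dtype=float)
        if len(w) != n:
            raise ValueError("case_weights must match series length")
    else:
        w = np.ones(n)

    if not isinstance(config.span, str):  # fixed-span mode
        fitted, _ = _local_linear(x, y, w, _half_width(float(config.span), n))
        return fitted

    halves = [_half_width(s, n) for s in SPANS]
    mid_half = halves[1]
    fits = []
    resids = []
    for h in halves:
        fitted, cv = _local_linear(x, y, w, h)
        fits.append(fitted)
        # smooth |CV residual| with the midrange span before comparison
        smoothed_resid, _ = _local_linear(x, np.abs(cv), w, mid_half)
        resids.append(smoothed_resid)
    resids = np.vstack(resids)  # 3 x n

    # per-point best span; ties in CV residual resolved toward the larger span
    best_k = (len(SPANS) - 1) - np.argmin(resids[::-1], axis=0)
    best_span = np.asarray(SPANS)[best_k]
    if config.bass > 0:
        alpha = min(config.bass, 10.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                resids[-1] > 0, resids[best_k, np.arange(n)] / resids[-1], 1.0
            )
        ratio = np.clip(ratio, 0.0, 1.0)
        best_span = best_span + (SPANS[-1] - best_span) * ratio ** (10.0 - alpha)

    # smooth the selected spans, then interpolate between span-level fits
    span_smooth, _ = _local_linear(x, best_span, w, mid_half)
    span_smooth = np.clip(span_smooth, SPANS[0], SPANS[-1])
    fitted = np.empty(n)
    for k in range(len(SPANS) - 1):
        s0, s1 = SPANS[k], SPANS[k + 1]
        mask = (span_smooth >= s0) & (span_smooth <= s1)
        if not np.any(mask):
            continue
        frac = (span_smooth[mask] - s0) / (s1 - s0)
        fitted[mask] = (1 - frac) * fits[k][mask] + frac * fits[k + 1][mask]
    # final pass with the tweeter span smooths the interpolation seams
    fitted, _ = _local_linear(x, fitted, w, halves[0])
    return fitted


# ---------------------------------------------------------------------------
# Detrending


def fit_growth_curve(raw: RingSeries, config: DetrendConfig | None = None):
    """Fitted growth curve of one core; mean fallback for short series."""
    if len(raw) < MIN_SMOOTH_LENGTH:
        warnings.warn(
            f"series {raw.series_id} shorter than {MIN_SMOOTH_LENGTH}; "
            "detrending by the series mean",
            stacklevel=2,
        )
        return np.full(len(raw), float(np.mean(raw.widths)))
    x = np.arange(len(raw), dtype=float)  # cambial age proxy
    return supersmooth(x, raw.widths, config)


def detrend_series(raw: RingSeries, fitted: np.ndarray) -> np.ndarray:
    """Ratio detrending: standardized index = raw width / fitted curve.

    Non-positive fitted values are floored at a small positive epsilon (with
    a warning) so the index stays defined and positive.
    """
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != raw.widths.shape:
        raise ValueError("fitted curve must align with the raw series")
    eps = 1e-6 * float(np.median(raw.widths))
    if np.any(fitted <= 0):
        warnings.warn(
            f"series {raw.series_id}: non-positive fitted values floored",
            stacklevel=2,
        )
        fitted = np.maximum(fitted, eps)
    return raw.widths / fitted


# ---------------------------------------------------------------------------
# Tukey biweight robust mean


def biweight_mean(
    values: Sequence[float], config: ChronologyConfig | None = None
) -> float:
    """Tukey's biweight location estimate.

    Iterates ``m <- sum(w*v)/sum(w)`` with ``u = (v - m)/(c*S)``, ``S`` the
    median absolute deviation from the current ``m`` and bisquare weights
    ``w = (1 - u^2)^2`` for |u| < 1 (zero otherwise), starting from the
    median.  Falls back to the median for fewer than four values.
    """
    config = config or ChronologyConfig()
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("biweight_mean requires at least one finite value")
    m = float(np.median(v))
    if len(v) < MIN_BIWEIGHT_N:
        return m
    c = config.biweight_c
    for _ in range(config.biweight_max_iter):
        s = float(np.median(np.abs(v - m)))
        if s <= 0:
            return m
        u = (v - m) / (c * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() <= 0:
            return m
        m_new = float(np.sum(w * v) / np.sum(w))
        if abs(m_new - m) < config.biweight_tol:
            return m_new
        m = m_new
    return m


# ---------------------------------------------------------------------------
# Autoregressive pre-whitening


def _ar_fit(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Yule-Walker AR coefficients and innovation variance (demeaned input)."""
    if order == 0:
        return np.empty(0), float(np.mean(x**2))
    # biased (denominator-n) autocovariances: the standard Yule-Walker
    # choice, stable at high orders on short series
    rho, sigma = yule_walker(x, order=order, method="mle", demean=False)
    return rho, float(sigma**2)


def select_ar_order(x: np.ndarray, config: ChronologyConfig) -> int:
    """AR order in 0..max chosen by the configured information criterion."""
    n = len(x)
    pmax = config.max_order(n)
    best_p, best_ic = 0, np.inf
    for p in range(pmax + 1):
        try:
            _, s2 = _ar_fit(x, p)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate input
            continue
        if s2 <= 0:
            continue
        penalty = 2.0 * p if config.ar_criterion == "aic" else np.log(n) * p
        ic = n * np.log(s2) + penalty
        if ic < best_ic - 1e-12:
            best_ic, best_p = ic, p
    return best_p


def prewhiten(
    series: Sequence[float], config: ChronologyConfig | None = None
) -> tuple[np.ndarray, int]:
    """Remove serial autocorrelation with an autoregressive fit.

    The AR order p is chosen by information criterion (AIC by default) over
    0..max; residuals of the Yule-Walker fit are returned with the series
    mean added back, aligned to positions p+1..n of the input.  Order 0
    returns the series unchanged.

    Returns
    -------
    (residual series, selected order p)
    """
    config = config or ChronologyConfig()
    x = np.asarray(series, dtype=float)
    n = len(x)
    if np.any(~np.isfinite(x)):
        raise ValueError("prewhiten requires a gap-free series")
    if np.ptp(x) == 0:
        warnings.warn("constant series left unchanged by prewhiten",
                      stacklevel=2)
        return x.copy(), 0
    if n <= 2:
        return x.copy(), 0
    mean = float(np.mean(x))
    xc = x - mean
    p = select_ar_order(xc, config)
    if p == 0:
        return x.copy(), 0
    rho, _ = _ar_fit(xc, p)
    pred = np.zeros(n - p)
    for j in range(1, p + 1):
        pred += rho[j - 1] * xc[p - j : n - j]
    resid = xc[p:] - pred
    # re-centre so the output mean matches the input mean exactly
    return resid - resid.mean() + mean, p


# ---------------------------------------------------------------------------
# Chronology assembly


def build_chronology(
    cores: Sequence[RingSeries],
    dconf: DetrendConfig | None = None,
    cconf: ChronologyConfig | None = None,
) -> Chronology:
    """Detrend each core, pre-whiten each detrended index, and combine cores
    into one site chronology with a per-year biweight mean.

    Cores need not cover the same years; each year's value averages whatever
    cores are present (sample depth recorded), and years with no core are
    absent from the result.
    """
    cconf = cconf or ChronologyConfig()
    if len(cores) == 0:
        raise ValueError("build_chronology needs at least one core")
    site = cores[0].site_id
    per_core: list[tuple[int, np.ndarray]] = []  # (first_year, index values)
    for core in cores:
        if core.site_id != site:
            raise ValueError("all cores must belong to the same site")
        fitted = fit_growth_curve(core, dconf)
        index = detrend_series(core, fitted)
        first = core.first_year
        if cconf.prewhiten and cconf.prewhiten_per_core:
            index, p = prewhiten(index, cconf)
            first += p
        per_core.append((first, index))

    y0 = min(f for f, _ in per_core)
    y1 = max(f + len(v) - 1 for f, v in per_core)
    n = y1 - y0 + 1
    stack = np.full((len(per_core), n), np.nan)
    for row, (f, v) in enumerate(per_core):
        stack[row, f - y0 : f - y0 + len(v)] = v
    depth = np.sum(np.isfinite(stack), axis=0)
    years = np.arange(y0, y1 + 1)
    keep = depth >= 1
    index = np.array(
        [biweight_mean(stack[:, j], cconf) for j in np.flatnonzero(keep)]
    )
    years, depth = years[keep], depth[keep]
    # a core gap (possible after ragged pre-whitening) would break year
    # consecutiveness; trim to the longest contiguous run ending latest
    if len(years) and np.any(np.diff(years) != 1):  # pragma: no cover
        breaks = np.flatnonzero(np.diff(years) != 1)
        start = breaks[-1] + 1
        years, index, depth = years[start:], index[start:], depth[start:]
    chron = Chronology(site, years, index, depth)
    if cconf.prewhiten and not cconf.prewhiten_per_core:
        whitened, p = prewhiten(chron.index, cconf)
        chron = Chronology(
            site, chron.years[p:], whitened, chron.sample_depth[p:]
        )
    return chron
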
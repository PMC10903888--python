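"""Configuration objects for simulation, chronology building and validation.

All year values are inclusive calendar years; months are 1-based (January = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import yaml

#: Default monthly mean precipitation, mm (temperate mid-latitude regime with a
#: summer maximum; 12 values, January..December).
DEFAULT_SEASONAL_MEAN = (
    50.0, 45.0, 55.0, 65.0, 75.0, 85.0, 90.0, 80.0, 70.0, 65.0, 60.0, 55.0
)

#: Default lag-month response weights, oldest -> newest of the 8-month window.
#: Late-window (growing-season) months carry more weight than the preceding
#: winter, as is typical for moisture-limited tree growth.
DEFAULT_RESPONSE_WEIGHTS = (0.05, 0.05, 0.10, 0.10, 0.15, 0.20, 0.20, 0.15)

ProductNoise = Union[float, Mapping[str, float]]


@dataclass
class SimConfig:
    """Parameters of a synthetic validation study.

    The generator plants a known quality ordering among candidate
    precipitation products: each product perturbs the latent "true" monthly
    precipitation with multiplicative lognormal noise whose log-scale standard
    deviation is ``product_noise_sd[k]`` (optionally region-specific via a
    mapping ``{region: sd}``).  Smaller noise means a better product, so every
    downstream stage has a parameter-recovery target.
    """

    n_sites: int = 100
    n_regions: int = 1
    years: tuple[int, int] = (1921, 2000)
    n_products: int = 3
    product_noise_sd: Sequence[ProductNoise] = (0.25, 0.5, 1.0)
    seasonal_mean: Sequence[float] = DEFAULT_SEASONAL_MEAN
    seasonal_cv: float = 0.4
    response_weights: Sequence[float] = DEFAULT_RESPONSE_WEIGHTS
    growth_noise_sd: float = 0.3
    ar1_coef: float = 0.3
    age_trend: tuple[float, float] = (2.0, 0.03)
    n_cores_per_site: int = 5
    core_noise_sd: float = 0.25
    evi_missing_frac: float = 0.1
    hemisphere_split: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 - y0 + 1 < 30:
            raise ValueError("year span must cover at least 30 years")
        if self.n_products < 2:
            raise ValueError("need at least 2 candidate products to rank")
        if len(self.product_noise_sd) != self.n_products:
            raise ValueError("product_noise_sd must have one entry per product")
        for sd in self.product_noise_sd:
            vals = sd.values() if isinstance(sd, Mapping) else [sd]
            if any(v < 0 for v in vals):
                raise ValueError("product_noise_sd values must be >= 0")
        if len(self.seasonal_mean) != 12:
            raise ValueError("seasonal_mean needs 12 monthly values")
        if any(m <= 0 for m in self.seasonal_mean):
            raise ValueError("seasonal_mean entries must be strictly positive")
        if len(self.response_weights) != 8:
            raise ValueError("response_weights must have exactly 8 entries")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if not 0 <= self.evi_missing_frac < 1:
            raise ValueError("evi_missing_frac must lie in [0, 1)")
        if not 0 <= self.hemisphere_split <= 1:
            raise ValueError("hemisphere_split must lie in [0, 1]")
        if self.seasonal_cv < 0:
            raise ValueError("seasonal_cv must be >= 0")
        if self.n_sites < 1 or self.n_cores_per_site < 1:
            raise ValueError("n_sites and n_cores_per_site must be >= 1")

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1

    def noise_sd(self, product_index: int, region: str) -> float:
        """Log-noise scale for one product in one region."""
        sd = self.product_noise_sd[product_index]
        if isinstance(sd, Mapping):
            return float(sd[region])
        return float(sd)


@dataclass
class DetrendConfig:
    """Supersmoother settings used when detrending a ring-width series.

    ``span`` is either ``"cv"`` (variable span chosen per point by
    cross-validation, the default) or a fixed fraction of the series length in
    (0, 1].  ``bass`` >= 0 biases the cross-validated span choice toward
    smoother (larger-span) fits.  ``case_weights``, when given, must be
    positive and as long as the series being smoothed.
    """

    span: Union[str, float] = "cv"
    bass: float = 0.0
    case_weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if isinstance(self.span, str):
            if self.span != "cv":
                raise ValueError("span must be 'cv' or a fraction in (0, 1]")
        elif not 0 < float(self.span) <= 1:
            raise ValueError("fixed span must lie in (0, 1]")
        if self.bass < 0:
            raise ValueError("bass must be >= 0")
        if self.case_weights is not None and any(
            w <= 0 for w in self.case_weights
        ):
            raise ValueError("case weights must be strictly positive")


@dataclass
class ChronologyConfig:
    """Settings for robust averaging and pre-whitening of detrended cores."""

    biweight_c: float = 9.0
    biweight_tol: float = 1e-8
    biweight_max_iter: int = 50
    prewhiten: bool = True
    #: Pre-whiten each detrended core before averaging (default) rather than
    #: the averaged chronology; set False to whiten the site average instead.
    prewhiten_per_core: bool = True
    ar_max_order: int | None = None
    ar_criterion: str = "aic"

    def __post_init__(self) -> None:
        if self.biweight_c <= 0:
            raise ValueError("biweight_c must be > 0")
        if self.biweight_tol <= 0:
            raise ValueError("biweight_tol must be > 0")
        if self.ar_criterion not in ("aic", "bic"):
            raise ValueError("ar_criterion must be 'aic' or 'bic'")

    def max_order(self, n: int) -> int:
        """AR order cap: min(round(10*log10(n)), n - 2) unless overridden."""
        cap = min(int(round(10 * np.log10(n))), n - 2)
        if self.ar_max_order is not None:
            cap = min(cap, self.ar_max_order)
        return max(cap, 0)


@dataclass
class ValidationConfig:
    """Moving-window and full-period regression scoring settings.

    The defaults reproduce the standard layout: 21-year windows advanced in
    single-year steps across 1901-2000, reported at window midpoints
    1911..1990.
    """

    window_length: int = 21
    window_step: int = 1
    min_obs_full: int = 20
    require_complete_window: bool = True
    eval_span: tuple[int, int] = (1901, 2000)

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd (midpoint well-defined)")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")
        if self.min_obs_full <= 9:
            raise ValueError(
                "min_obs_full must exceed 9 (8 predictors + intercept)"
            )


@dataclass
class StudyConfig:
    """Bundle of all stage configurations, loadable from one YAML file."""

    sim: SimConfig = field(default_factory=SimConfig)
    detrend: DetrendConfig = field(default_factory=DetrendConfig)
    chronology: ChronologyConfig = field(default_factory=ChronologyConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    prewhiten_evi: bool = False


def _coerce(section: dict, cls):
    known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
    bad = set(section) - known
    if bad:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    for key in ("years", "eval_span", "age_trend"):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    return cls(**section)


def load_config(path) -> StudyConfig:
    """Read a StudyConfig from a YAML file with sections sim/detrend/
    chronology/validation (all optional; omitted sections take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    return StudyConfig(
        sim=_coerce(raw.get("sim", {}), SimConfig),
        detrend=_coerce(raw.get("detrend", {}), DetrendConfig),
        chronology=_coerce(raw.get("chronology", {}), ChronologyConfig),
        validation=_coerce(raw.get("validation", {}), ValidationConfig),
        prewhiten_evi=bool(raw.get("prewhiten_evi", False)),
    )
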
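"""End-to-end orchestration: synthetic study (or loaded inputs) through
chronology building, design assembly, R² scoring and regional ranking."""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .alignment import build_design, pairwise_complete
from .chronology import build_chronology
from .config import StudyConfig
from .ranking import RegionalOutcome, regional_report
from .simulate import simulate_study
from .types import ClimateTable, Chronology, LaggedDesign, RingSeries
from .validation import full_period_validation, moving_window_validation

log = logging.getLogger(__name__)


def build_chronologies(
    ring_series: Mapping[str, list[RingSeries]], config: StudyConfig
) -> dict[str, Chronology]:
    return {
        site: build_chronology(cores, config.detrend, config.chronology)
        for site, cores in sorted(ring_series.items())
    }


def chronologies_frame(chrons: Mapping[str, Chronology]) -> pd.DataFrame:
    rows = []
    for site in sorted(chrons):
        c = chrons[site]
        for y, v, d in zip(c.years, c.index, c.sample_depth):
            rows.append(
                {"site_id": site, "year": int(y), "index": float(v),
                 "sample_depth": int(d)}
            )
    return pd.DataFrame(rows,
                        columns=["site_id", "year", "index", "sample_depth"])


def assemble_designs(
    responses: Mapping[str, pd.Series],
    climate: ClimateTable,
    hemisphere_of: Mapping[str, str],
) -> dict[str, dict[str, LaggedDesign]]:
    """Pairwise-complete lagged designs per site x product.

    ``responses`` maps site -> annual growth/greenness series indexed by
    growth year.  Sites whose pairwise-complete designs are empty are
    dropped (logged).
    """
    products = climate.products
    # one groupby pass instead of repeated dataframe filtering
    monthly: dict[tuple[str, str], pd.Series] = {
        (site, prod): grp.set_index(["year", "month"])["precip_mm"].sort_index()
        for (site, prod), grp in climate.df.groupby(["site_id", "product"])
    }
    out: dict[str, dict[str, LaggedDesign]] = {}
    for site in sorted(responses):
        growth = responses[site]
        growth = growth.rename(site)
        designs = {}
        usable = True
        for pid in products:
            key = (site, pid)
            if key not in monthly:
                usable = False
                break
            designs[pid] = build_design(growth, monthly[key], pid,
                                        hemisphere_of[site])
        if not usable:
            log.warning("site %s lacks climate coverage; skipped", site)
            continue
        trimmed = pairwise_complete(designs)
        if next(iter(trimmed.values())).n_obs == 0:
            log.warning("site %s: empty pairwise-complete design", site)
            continue
        out[site] = trimmed
    return out


def run_study(config: StudyConfig):
    """Run the full synthetic pipeline; returns a results bundle.

    Returns a dict with the synthetic study, the chronologies, the
    full-period and moving-window results frames (tree-ring and greenness
    responses) and the per-region Condorcet outcomes for each response type.
    """
    study = simulate_study(config.sim)
    chrons = build_chronologies(study.ring_series, config)
    responses = {s: c.as_series() for s, c in chrons.items()}
    designs = assemble_designs(responses, study.products,
                               study.hemisphere_of)
    full = full_period_validation(designs, config.validation)
    windows = moving_window_validation(designs, config.validation)
    outcomes = regional_report(full, study.region_of)

    evi_responses = dict(study.evi_series)
    if config.prewhiten_evi:
        from .chronology import prewhiten

        whitened = {}
        for site, series in evi_responses.items():
            filled = series.dropna()
            vals, p = prewhiten(filled.to_numpy(), config.chronology)
            whitened[site] = pd.Series(vals, index=filled.index[p:])
        evi_responses = whitened
    evi_designs = assemble_designs(evi_responses, study.products,
                                   study.hemisphere_of)
    evi_full = full_period_validation(evi_designs, config.validation)
    evi_outcomes = (
        regional_report(evi_full, study.region_of) if len(evi_full) else []
    )
    return {
        "study": study,
        "chronologies": chrons,
        "designs": designs,
        "full_results": full,
        "window_results": windows,
        "outcomes": outcomes,
        "evi_full_results": evi_full,
        "evi_outcomes": evi_outcomes,
    }


def run_full_period(config: StudyConfig):
    """Tree-ring branch only, full-period scores and regional ranking.

    Lighter than :func:`run_study` (no moving windows, no greenness branch);
    used for repeated parameter-recovery experiments.
    """
    study = simulate_study(config.sim)
    chrons = build_chronologies(study.ring_series, config)
    responses = {s: c.as_series() for s, c in chrons.items()}
    designs = assemble_designs(responses, study.products,
                               study.hemisphere_of)
    full = full_period_validation(designs, config.validation)
    outcomes = regional_report(full, study.region_of)
    return {"study": study, "designs": designs, "full_results": full,
            "outcomes": outcomes}


def winners_by_region(outcomes: list[RegionalOutcome]) -> dict[str, str | None]:
    return {o.region: o.winner for o in outcomes}
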
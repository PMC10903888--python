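"""Condorcet ranked-ballot ranking of candidate products per region.

Each site (or pixel) contributes one ranked ballot: its products ordered by
descending regression skill (R²), exact ties sharing a rank.  Within a
region, products are compared pairwise across ballots; a Condorcet winner
beats every other product head-to-head, a Condorcet loser loses to every
other.  A majority cycle yields no winner; Copeland scores (pairwise wins
minus losses) are reported as a diagnostic rather than silently electing a
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: A ballot maps product_id -> rank (1 = best; ties share a rank).
Ballot = dict[str, int]

#: Fewer ballots than this flags a region's outcome as weakly supported.
MIN_BALLOTS = 5


@dataclass
class RegionalOutcome:
    region: str
    n_ballots: int
    products: list[str]
    winner: str | None
    loser: str | None
    copeland_scores: dict[str, int]
    margins: dict[tuple[str, str], float]  # fraction of ballots a beats b
    used_fallback: bool
    low_n: bool = False
    mean_r2: dict[str, float] = field(default_factory=dict)


def ballots_from_scores(scores: Mapping[str, float]) -> Ballot:
    """Rank products by descending score; exact ties share a rank.

    Any missing (NaN) score invalidates the ballot (raises), enforcing the
    balance contract that every product is scored on the same data.
    """
    if len(scores) < 2:
        raise ValueError("a ballot needs at least 2 products")
    for pid, val in scores.items():
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise ValueError(f"missing score for product {pid}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    ballot: Ballot = {}
    rank = 0
    prev = None
    for i, (pid, val) in enumerate(ordered):
        if prev is None or val < prev:
            rank = i + 1
        ballot[pid] = rank
        prev = val
    return ballot


def pairwise_tally(
    ballots: Sequence[Ballot], products: Sequence[str] | None = None
) -> pd.DataFrame:
    """Strict-preference counts: tally.loc[a, b] = number of ballots ranking
    a strictly above b.  Ties on a ballot count for neither side."""
    if len(ballots) == 0:
        raise ValueError("need at least one ballot")
    if products is None:
        products = sorted(ballots[0])
    products = list(products)
    tally = pd.DataFrame(0, index=products, columns=products, dtype=int)
    for ballot in ballots:
        if set(ballot) != set(products):
            raise ValueError("ballot product set mismatch")
        for a in products:
            ra = ballot[a]
            for b in products:
                if a != b and ra < ballot[b]:
                    tally.loc[a, b] += 1
    return tally


def condorcet_outcome(
    tally: pd.DataFrame, n_ballots: int, region: str = ""
) -> RegionalOutcome:
    """Winner/loser from a pairwise tally, with Copeland diagnostics.

    The winner (if any) beats every other product pairwise; the loser loses
    every contest.  When a majority cycle leaves no winner, ``winner`` is
    None and ``used_fallback`` is set, with Copeland scores available for
    downstream tie-breaking.
    """
    products = list(tally.index)
    if len(products) < 2:
        raise ValueError("need at least 2 products")
    copeland = {p: 0 for p in products}
    beats = {p: 0 for p in products}
    losses = {p: 0 for p in products}
    margins: dict[tuple[str, str], float] = {}
    for a in products:
        for b in products:
            if a == b:
                continue
            margins[(a, b)] = (
                tally.loc[a, b] / n_ballots if n_ballots else 0.0
            )
            if tally.loc[a, b] > tally.loc[b, a]:
                copeland[a] += 1
                beats[a] += 1
            elif tally.loc[a, b] < tally.loc[b, a]:
                copeland[a] -= 1
                losses[a] += 1
    full = len(products) - 1
    winners = [p for p in products if beats[p] == full]
    losers = [p for p in products if losses[p] == full]
    winner = winners[0] if winners else None
    loser = losers[0] if losers else None
    return RegionalOutcome(
        region=region,
        n_ballots=n_ballots,
        products=products,
        winner=winner,
        loser=loser,
        copeland_scores=copeland,
        margins=margins,
        used_fallback=winner is None,
    )


def regional_report(
    fit_results: pd.DataFrame,
    region_of: Mapping[str, str],
    min_ballots: int = MIN_BALLOTS,
    agg: str = "mean",
) -> list[RegionalOutcome]:
    """Per-region Condorcet outcome plus per-product aggregate R².

    ``fit_results`` is a full-period results frame (columns site_id,
    product_id, window == "full", r_squared, n_obs); sites are grouped by
    their region label.  Regions with fewer than ``min_ballots`` ballots are
    flagged via ``low_n``.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    full = fit_results[fit_results["window"].astype(str) == "full"]
    products = sorted(full["product_id"].unique())
    regions: dict[str, list[Ballot]] = {}
    r2_rows: dict[str, list[pd.Series]] = {}
    for site, grp in full.groupby("site_id"):
        if site not in region_of:
            raise ValueError(f"site {site} has no region label")
        scores = grp.set_index("product_id")["r_squared"]
        if set(scores.index) != set(products):
            raise ValueError(f"site {site} lacks scores for all products")
        region = region_of[site]
        regions.setdefault(region, []).append(ballots_from_scores(scores))
        r2_rows.setdefault(region, []).append(scores)
    outcomes = []
    for region in sorted(regions):
        ballots = regions[region]
        tally = pairwise_tally(ballots, products)
        outcome = condorcet_outcome(tally, len(ballots), region)
        outcome.low_n = len(ballots) < min_ballots
        r2 = pd.concat(r2_rows[region], axis=1)
        outcome.mean_r2 = (
            r2.mean(axis=1) if agg == "mean" else r2.median(axis=1)
        ).to_dict()
        outcomes.append(outcome)
    return outcomes


def report_frame(outcomes: Sequence[RegionalOutcome]) -> pd.DataFrame:
    """Flatten regional outcomes into the rank-report table schema."""
    rows = []
    for o in outcomes:
        row = {
            "region": o.region,
            "n_ballots": o.n_ballots,
            "winner": o.winner if o.winner is not None else "none",
            "loser": o.loser if o.loser is not None else "none",
            "used_fallback": o.used_fallback,
            "low_n": o.low_n,
        }
        for p in o.products:
            row[f"copeland_{p}"] = o.copeland_scores[p]
        for p in o.products:
            row[f"mean_r2_{p}"] = o.mean_r2.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
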
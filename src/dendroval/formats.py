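"""File formats: Tucson decadal RWL ring-width files and the project's
delimited tables (climate, chronology, greenness, regions, results).

Two RWL precision dialects occur in ITRDB archives and both are supported:
widths stored as integer hundredths of a millimetre with series terminator
``999``, or thousandths with terminator ``-9999``.  The dialect of a file is
auto-detected from the terminator (a ``-9999`` anywhere marks the thousandths
dialect) and can be overridden explicitly.

Parsers reject structurally invalid input rather than repairing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import CLIMATE_COLUMNS, ClimateTable, RingSeries

#: dialect name -> (multiplier from mm to stored integer, terminator value)
DIALECTS = {"0.01": (100, 999), "0.001": (1000, -9999)}

RESULT_COLUMNS = ["site_id", "product_id", "window", "r_squared", "n_obs"]
REGION_COLUMNS = ["site_id", "region", "hemisphere"]
CHRONOLOGY_COLUMNS = ["site_id", "year", "index", "sample_depth"]
EVI_COLUMNS = ["site_id", "year", "value"]


class RwlFormatError(ValueError):
    """Raised on malformed Tucson RWL content."""


@dataclass
class RwlDocument:
    """Parsed RWL file: (series_id, first_year, widths in mm) per series."""

    series: list[tuple[str, int, np.ndarray]]
    precision_dialect: str = "0.01"

    def __post_init__(self) -> None:
        if self.precision_dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.precision_dialect!r}")
        seen = set()
        for sid, first_year, values in self.series:
            if sid in seen:
                raise ValueError(f"duplicate series id {sid!r}")
            seen.add(sid)

    def to_ring_series(self, site_id: str) -> list[RingSeries]:
        return [
            RingSeries(site_id, sid, fy, vals) for sid, fy, vals in self.series
        ]


def document_from_series(
    cores: Iterable[RingSeries], dialect: str = "0.01"
) -> RwlDocument:
    """Build an RwlDocument, quantizing widths to the dialect precision."""
    mult, _ = DIALECTS[dialect]
    series = [
        (c.series_id, c.first_year, np.round(c.widths * mult) / mult)
        for c in cores
    ]
    return RwlDocument(series, dialect)


def _decade_end(year: int) -> int:
    return year - year % 10 + 9


def read_rwl(path, dialect: str | None = None) -> RwlDocument:
    """Parse a Tucson decadal RWL file.

    Parameters
    ----------
    path : path-like
    dialect : {"0.01", "0.001"}, optional
        Force a precision dialect instead of auto-detecting from the
        terminator value.
    """
    lines = Path(path).read_text().splitlines()
    parsed = []  # (lineno, sid, year, int tokens)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        sid = line[:8].strip()
        rest = line[8:].split()
        if not sid or len(rest) < 2:
            raise RwlFormatError(
                f"line {lineno}: expected series id, year and values"
            )
        try:
            year = int(rest[0])
            vals = [int(tok) for tok in rest[1:]]
        except ValueError as exc:
            raise RwlFormatError(f"line {lineno}: non-integer field") from exc
        if len(vals) > 10:
            raise RwlFormatError(
                f"line {lineno}: more than 10 values in a decade line"
            )
        parsed.append((lineno, sid, year, vals))

    if dialect is None:
        has_neg = any(-9999 in vals for _, _, _, vals in parsed)
        dialect = "0.001" if has_neg else "0.01"
    mult, term = DIALECTS[dialect]

    series: list[tuple[str, int, np.ndarray]] = []
    state: dict[str, dict] = {}  # open series: sid -> {first, values, next}
    closed: set[str] = set()
    for lineno, sid, year, vals in parsed:
        if sid in closed:
            raise RwlFormatError(
                f"line {lineno}: series {sid!r} re-opened after terminator"
            )
        if sid not in state:
            state[sid] = {"first": year, "values": [], "next": year}
        st = state[sid]
        if year < st["next"]:
            raise RwlFormatError(
                f"line {lineno}: overlapping decades in series {sid!r}"
            )
        if year > st["next"]:
            raise RwlFormatError(
                f"line {lineno}: gap in years of series {sid!r} "
                f"(expected {st['next']}, got {year})"
            )
        ended = False
        for k, v in enumerate(vals):
            if ended:
                raise RwlFormatError(
                    f"line {lineno}: data after terminator in series {sid!r}"
                )
            if v == term:
                ended = True
                continue
            if v < 0:
                raise RwlFormatError(
                    f"line {lineno}: negative measurement {v} in {sid!r}"
                )
            y = year + k
            if y > _decade_end(year):
                raise RwlFormatError(
                    f"line {lineno}: values run past the decade in {sid!r}"
                )
            st["values"].append(v / mult)
            st["next"] = y + 1
        if ended:
            if not st["values"]:
                raise RwlFormatError(
                    f"line {lineno}: series {sid!r} has no measurements"
                )
            series.append(
                (sid, st["first"], np.asarray(st["values"], dtype=float))
            )
            closed.add(sid)
            del state[sid]
    if state:
        sid = next(iter(state))
        raise RwlFormatError(f"series {sid!r} not terminated")
    return RwlDocument(series, dialect)


def write_rwl(doc: RwlDocument, path) -> None:
    """Write a Tucson decadal RWL file in the document's dialect."""
    mult, term = DIALECTS[doc.precision_dialect]
    out = []
    for sid, first_year, values in doc.series:
        if len(sid) > 8:
            raise ValueError(f"series id {sid!r} exceeds 8 characters")
        if first_year < 0:
            raise ValueError("BCE years are not supported by this writer")
        stored = np.round(np.asarray(values, dtype=float) * mult).astype(int)
        if np.any(stored < 0):
            raise ValueError(f"series {sid!r} has negative widths")
        tokens = [int(v) for v in stored] + [term]
        year = first_year
        pos = 0
        while pos < len(tokens):
            slots = _decade_end(year) - year + 1
            chunk = tokens[pos : pos + slots]
            line = f"{sid:<8}{year:4d}" + "".join(f"{v:6d}" for v in chunk)
            out.append(line)
            pos += len(chunk)
            year = _decade_end(year) + 1
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Delimited tables


def _read_table(path, columns: Sequence[str], dtypes: dict) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df.loc[:, list(columns)]
    for col, dt in dtypes.items():
        df[col] = df[col].astype(dt)
    return df


def read_climate_table(path) -> ClimateTable:
    """Read a long-format climate CSV (site_id, product, year, month,
    precip_mm) with strict schema and key validation."""
    df = _read_table(
        path,
        CLIMATE_COLUMNS,
        {"site_id": str, "product": str, "year": int, "month": int,
         "precip_mm": float},
    )
    return ClimateTable(df)


def write_climate_table(table: ClimateTable, path) -> None:
    table.sorted_frame().to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a validation-results table: one row per fit, with ``window``
    either the literal string "full" or a window midpoint year."""
    df = _read_table(
        path,
        RESULT_COLUMNS,
        {"site_id": str, "product_id": str, "window": str,
         "r_squared": float, "n_obs": int},
    )
    bad = df[(df["r_squared"] < 0) | (df["r_squared"] > 1)]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"r_squared outside [0, 1] for ({row.site_id}, {row.product_id})"
        )
    dup = df.duplicated(["site_id", "product_id", "window"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate result key ({row.site_id}, {row.product_id}, "
            f"{row.window})"
        )
    return df


def write_results(df: pd.DataFrame, path) -> None:
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results frame missing columns {missing}")
    out = df.loc[:, RESULT_COLUMNS].copy()
    out["window"] = out["window"].astype(str)
    out.to_csv(path, index=False)


def read_regions(path) -> pd.DataFrame:
    df = _read_table(
        path, REGION_COLUMNS, {"site_id": str, "region": str, "hemisphere": str}
    )
    bad = ~df["hemisphere"].isin(["N", "S"])
    if bad.any():
        raise ValueError(
            f"hemisphere must be 'N' or 'S' (site {df.loc[bad].iloc[0].site_id})"
        )
    if df["site_id"].duplicated().any():
        raise ValueError("duplicate site_id in regions table")
    return df


def write_regions(df: pd.DataFrame, path) -> None:
    df.loc[:, REGION_COLUMNS].to_csv(path, index=False)


def read_chronology_table(path) -> pd.DataFrame:
    return _read_table(
        path,
        CHRONOLOGY_COLUMNS,
        {"site_id": str, "year": int, "index": float, "sample_depth": int},
    )


def write_chronology_table(df: pd.DataFrame, path) -> None:
    df.loc[:, CHRONOLOGY_COLUMNS].to_csv(path, index=False)


def read_evi_table(path) -> pd.DataFrame:
    """Greenness table: site_id, year, value; blank values are missing."""
    return _read_table(
        path, EVI_COLUMNS, {"site_id": str, "year": int, "value": float}
    )


def write_evi_table(df: pd.DataFrame, path) -> None:
    df.loc[:, EVI_COLUMNS].to_csv(path, index=False)
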
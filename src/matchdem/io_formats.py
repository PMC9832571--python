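"""Reading, validating and writing the three field tables.

The pipeline consumes three delimited-text tables:

* **floral surveys** — one flower count per plant taxon, plot and survey
  date;
* **nest records** — one completed trap nest, with its end-of-construction
  day, brood-cell count (possibly missing) and occupied cavity length
  (possibly missing);
* **pollen samples** — pollen grain counts per plant taxon for one brood
  cell extracted from a nest.

Calendar dates are expressed as whole days elapsed since the most recent
season anchor (1 July by default, the austral convention: the flowering and
nesting season of the study system spans the southern-hemisphere spring and
summer, so anchoring at mid-winter keeps every season inside one
``season_year``).

Column names in the files are mapped onto the canonical schema through a
*dialect*: a plain ``{canonical_name: file_column}`` mapping (optionally
loaded from YAML), which absorbs naming differences between field seasons.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

FLOWER_COLUMNS = ["season_year", "day", "site", "unit", "plant_taxon", "flower_count"]
NEST_COLUMNS = [
    "nest_id",
    "bee_taxon",
    "site",
    "season_year",
    "end_day",
    "brood_cells",
    "cavity_length",
]
POLLEN_COLUMNS = ["nest_id", "plant_taxon", "grain_count"]

DEFAULT_ANCHOR = "07-01"


def to_day_of_season(calendar_date, anchor: str = DEFAULT_ANCHOR) -> tuple[int, int]:
    """Convert a calendar date to (season_year, day-of-season).

    ``day`` counts whole days elapsed since the most recent anchor date
    (month-day string, default ``"07-01"``) on or before ``calendar_date``;
    ``season_year`` is the calendar year of that anchor.  The anchor date
    itself maps to day 0.

    >>> to_day_of_season("2008-07-01")
    (2008, 0)
    >>> to_day_of_season("2009-01-15")
    (2008, 198)
    """
    if isinstance(calendar_date, dt.datetime):
        d = calendar_date.date()
    elif isinstance(calendar_date, dt.date):
        d = calendar_date
    else:
        try:
            d = dt.date.fromisoformat(str(calendar_date))
        except ValueError as exc:
            raise ValidationError(f"malformed date: {calendar_date!r}") from exc
    try:
        month, day = (int(p) for p in str(anchor).split("-"))
        anchor_date = dt.date(d.year, month, day)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"invalid season anchor: {anchor!r}") from exc
    if d < anchor_date:
        anchor_date = dt.date(d.year - 1, month, day)
    return anchor_date.year, (d - anchor_date).days


def load_dialect(path) -> dict:
    """Load a ``{canonical: file_column}`` mapping from a YAML file."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise ConfigurationError(f"dialect file {path} must contain a mapping")
    return dict(mapping)


def _read_table(path, columns, dialect=None, optional=()) -> pd.DataFrame:
    dialect = dict(dialect or {})
    df = pd.read_csv(path)
    rename = {v: k for k, v in dialect.items()}
    df = df.rename(columns=rename)
    missing = [c for c in columns if c not in df.columns and c not in optional]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)} (check the dialect mapping)"
        )
    for col in optional:
        if col not in df.columns:
            df[col] = np.nan
    if df.empty:
        logger.warning("%s: file contains a header but no data rows", path)
    return df[list(columns)]


def _reject(mask: pd.Series, message: str):
    if mask.any():
        rows = list(np.flatnonzero(mask.to_numpy()))
        raise ValidationError(f"{message} (row{'s' if len(rows) > 1 else ''} {rows})", rows)


def read_floral_surveys(path, dialect=None) -> pd.DataFrame:
    """Read and validate a floral-survey table.

    Rejects negative flower counts and day values outside [0, 365] with a
    :class:`ValidationError` naming the offending rows.
    """
    df = _read_table(path, FLOWER_COLUMNS, dialect)
    df = df.astype({"season_year": int, "day": int, "flower_count": float})
    _reject(df["flower_count"] < 0, "negative flower_count")
    _reject(~df["day"].between(0, 365), "day outside [0, 365]")
    return df.reset_index(drop=True)


def read_nests(path, dialect=None) -> pd.DataFrame:
    """Read and validate a nest-record table.

    ``brood_cells`` and ``cavity_length`` may each be missing per row, but
    never both: a nest without a direct cell count must carry a cavity
    length so the count can be imputed downstream.
    """
    df = _read_table(
        path, NEST_COLUMNS, dialect, optional=("brood_cells", "cavity_length")
    )
    df = df.astype(
        {
            "season_year": int,
            "end_day": int,
            "brood_cells": float,
            "cavity_length": float,
        }
    )
    _reject(df["end_day"] < 0, "negative end_day")
    cells = df["brood_cells"]
    present = cells.notna()
    _reject(present & (cells < 1), "brood_cells must be >= 1 when present")
    _reject(
        present & (cells != cells.round()), "brood_cells must be an integer when present"
    )
    _reject(df["cavity_length"].notna() & (df["cavity_length"] < 0), "negative cavity_length")
    _reject(
        ~present & df["cavity_length"].isna(),
        "nest lacks both brood_cells and cavity_length",
    )
    _reject(df["nest_id"].duplicated(), "duplicated nest_id")
    return df.reset_index(drop=True)


def read_pollen(path, dialect=None) -> pd.DataFrame:
    """Read and validate a pollen-sample table."""
    df = _read_table(path, POLLEN_COLUMNS, dialect)
    df = df.astype({"grain_count": int})
    _reject(df["grain_count"] < 0, "negative grain_count")
    _reject(
        df.duplicated(subset=["nest_id", "plant_taxon"]),
        "duplicated (nest_id, plant_taxon) pair",
    )
    return df.reset_index(drop=True)


def write_floral_surveys(df: pd.DataFrame, path) -> None:
    df[FLOWER_COLUMNS].to_csv(path, index=False)


def write_nests(df: pd.DataFrame, path) -> None:
    out = df.copy()
    # keep integer appearance for whole-valued counts despite NaN holes
    out["brood_cells"] = out["brood_cells"].astype("Int64")
    cols = NEST_COLUMNS + [c for c in ("estimated",) if c in out.columns]
    out[cols].to_csv(path, index=False)


def write_pollen(df: pd.DataFrame, path) -> None:
    df[POLLEN_COLUMNS].to_csv(path, index=False)


def aggregate_flowers(df: pd.DataFrame, stratify_sites: bool = False) -> pd.DataFrame:
    """Sum per-plot flower counts to one count per (season, day, taxon).

    Sites are pooled by default; with ``stratify_sites`` the site column is
    retained as an extra grouping key.  Because phenology weights are
    relative, the weighted mean date is invariant to whether plot counts
    are summed or averaged.
    """
    keys = ["season_year", "day", "plant_taxon"]
    if stratify_sites:
        keys.insert(2, "site")
    return df.groupby(keys, as_index=False)["flower_count"].sum()
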
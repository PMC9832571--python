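"""Phenology estimation and nesting-flowering mismatch statistics.

The phenological position of a season's flowering (or nesting) is summarised
by the abundance-weighted mean date

    WMD = sum_i d_i * a_i / sum_i a_i,

the arithmetic mean of observation days d_i weighted by the relative
abundance a_i recorded on each day.  For example, flower counts of 10, 60
and 30 on days 60, 67 and 74 give 0.1*60 + 0.6*67 + 0.3*74 = 68.4.

A bee species' *main floral resources* are the minimal set of plant taxa
that, taken in descending order of pollen abundance across all examined
nests, jointly account for at least 85% of the pollen.  The flowering WMD
of that set is computed on the day-wise pooled flower counts of its taxa,
so each taxon contributes in proportion to its floral abundance.

Mismatch is the absolute difference in days between bee timing and the
resource flowering WMD — at the nest level, the end day of that nest's
construction; at the population level, the nesting WMD over all of the
species' nests that season (each nest weighted equally).  Seasons in which
a species built no nests carry no information about its phenology and are
excluded (callers receive ``None`` and the exclusion is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedPhenologyError

logger = logging.getLogger(__name__)

MAIN_RESOURCE_THRESHOLD = 0.85


@dataclass(frozen=True)
class PhenologyEstimate:
    """Abundance-weighted mean date for one taxon and season."""

    taxon: str
    season_year: int
    wmd: float
    total_abundance: float


@dataclass(frozen=True)
class MainResourceSet:
    """Plant taxa jointly holding >= ``threshold`` of a bee's pollen."""

    bee_taxon: str
    plant_taxa: tuple
    cumulative_share: float
    threshold: float = MAIN_RESOURCE_THRESHOLD


@dataclass(frozen=True)
class MismatchRecord:
    """Nest- or population-level mismatch, in absolute days."""

    scope: str  # "nest" or "population"
    key: str  # nest_id or bee_taxon
    season_year: int
    mismatch_days: float


def weighted_mean_date(observations: Sequence | None = None, abundances=None) -> float:
    """Abundance-weighted mean day.

    Accepts either a sequence of ``(day, abundance)`` pairs or two parallel
    arrays.  Raises :class:`UndefinedPhenologyError` when no positive
    abundance is present.

    >>> weighted_mean_date([(60, 10), (67, 60), (74, 30)])
    68.4
    """
    if abundances is None:
        obs = list(observations or [])
        if not obs:
            raise UndefinedPhenologyError("no observations")
        days = np.asarray([o[0] for o in obs], dtype=float)
        weights = np.asarray([o[1] for o in obs], dtype=float)
    else:
        days = np.asarray(observations, dtype=float)
        weights = np.asarray(abundances, dtype=float)
    if days.size == 0:
        raise UndefinedPhenologyError("no observations")
    if np.any(weights < 0):
        raise ContractError("negative abundance")
    total = weights.sum()
    if total <= 0:
        raise UndefinedPhenologyError("all abundances are zero")
    return float(np.dot(days, weights) / total)


def identify_main_resources(
    pollen_totals: Mapping[str, float],
    bee_taxon: str = "",
    threshold: float = MAIN_RESOURCE_THRESHOLD,
) -> MainResourceSet:
    """Greedy main-resource selection.

    Taxa are sorted by descending summed (standardized) pollen abundance —
    ties broken lexicographically by taxon name for determinism — and taken
    until the cumulative proportion first reaches ``threshold``.
    """
    totals = {t: float(a) for t, a in pollen_totals.items() if a > 0}
    if not totals:
        raise UndefinedPhenologyError(
            f"no positive pollen totals for bee taxon {bee_taxon!r}"
        )
    grand = sum(totals.values())
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    chosen: list[str] = []
    cumulative = 0.0
    for taxon, abundance in ordered:
        chosen.append(taxon)
        cumulative += abundance / grand
        if cumulative >= threshold:
            break
    return MainResourceSet(
        bee_taxon=bee_taxon,
        plant_taxa=tuple(chosen),
        cumulative_share=cumulative,
        threshold=threshold,
    )


def pooled_flowering_wmd(
    surveys: pd.DataFrame, resources: MainResourceSet, season_year: int
) -> PhenologyEstimate:
    """Flowering WMD of the pooled main-resource taxa in one season.

    Flower counts of all resource taxa are summed day-wise into one
    composite seasonal curve before the weighted mean is taken, so each
    taxon contributes in proportion to its floral abundance.
    """
    sub = surveys[
        (surveys["season_year"] == season_year)
        & surveys["plant_taxon"].isin(resources.plant_taxa)
    ]
    daily = sub.groupby("day")["flower_count"].sum()
    daily = daily[daily > 0]
    if daily.empty:
        raise UndefinedPhenologyError(
            f"no flowers of the main resources of {resources.bee_taxon!r} "
            f"recorded in season {season_year}"
        )
    wmd = weighted_mean_date(daily.index.to_numpy(), daily.to_numpy())
    return PhenologyEstimate(
        taxon=f"resources[{resources.bee_taxon}]",
        season_year=int(season_year),
        wmd=wmd,
        total_abundance=float(daily.sum()),
    )


def flowering_wmd_by_season(
    surveys: pd.DataFrame, resources: MainResourceSet
) -> dict[int, PhenologyEstimate]:
    """Per-season resource flowering WMDs; undefined seasons are logged and skipped."""
    out: dict[int, PhenologyEstimate] = {}
    for year in sorted(surveys["season_year"].unique()):
        try:
            out[int(year)] = pooled_flowering_wmd(surveys, resources, int(year))
        except UndefinedPhenologyError:
            logger.warning(
                "season %s excluded for %s: no main-resource flowers recorded",
                year,
                resources.bee_taxon,
            )
    return out


def nesting_wmd(nests: pd.DataFrame, bee_taxon: str, season_year: int) -> PhenologyEstimate:
    """Nesting WMD: mean end-of-construction day, one unit weight per nest."""
    days = nests.loc[
        (nests["bee_taxon"] == bee_taxon) & (nests["season_year"] == season_year),
        "end_day",
    ].to_numpy(dtype=float)
    if days.size == 0:
        raise UndefinedPhenologyError(
            f"no nests of {bee_taxon!r} in season {season_year}"
        )
    return PhenologyEstimate(
        taxon=bee_taxon,
        season_year=int(season_year),
        wmd=weighted_mean_date(days, np.ones_like(days)),
        total_abundance=float(days.size),
    )


def nest_mismatch(nest, flowering: PhenologyEstimate) -> MismatchRecord:
    """Absolute days between one nest's end day and the flowering WMD.

    ``nest`` is any mapping (e.g. a DataFrame row) with ``nest_id``,
    ``season_year`` and ``end_day``.  Both arguments must refer to the same
    season.
    """
    if int(nest["season_year"]) != flowering.season_year:
        raise ContractError(
            f"nest season {nest['season_year']} != flowering season "
            f"{flowering.season_year}"
        )
    return MismatchRecord(
        scope="nest",
        key=str(nest["nest_id"]),
        season_year=flowering.season_year,
        mismatch_days=abs(float(nest["end_day"]) - flowering.wmd),
    )


def population_mismatch(
    nests: pd.DataFrame, bee_taxon: str, flowering: PhenologyEstimate
) -> MismatchRecord | None:
    """Absolute days between the nesting WMD and the flowering WMD.

    Returns ``None`` (season excluded, logged) when the species built no
    nests that season.
    """
    try:
        nwmd = nesting_wmd(nests, bee_taxon, flowering.season_year)
    except UndefinedPhenologyError:
        logger.warning(
            "season %s excluded for %s: no nests recorded",
            flowering.season_year,
            bee_taxon,
        )
        return None
    return MismatchRecord(
        scope="population",
        key=bee_taxon,
        season_year=flowering.season_year,
        mismatch_days=abs(nwmd.wmd - flowering.wmd),
    )


def nest_mismatch_table(
    nests: pd.DataFrame, flowering: Mapping[int, PhenologyEstimate], bee_taxon: str
) -> pd.DataFrame:
    """Per-nest mismatch table for one bee species.

    Nests from seasons with an undefined resource flowering WMD are dropped
    (with a log entry); the returned frame keeps ``brood_cells`` alongside
    the mismatch so it can feed the recruitment models directly.
    """
    sub = nests[nests["bee_taxon"] == bee_taxon]
    rows = []
    for year, grp in sub.groupby("season_year"):
        est = flowering.get(int(year))
        if est is None:
            logger.warning(
                "season %s excluded for %s: flowering WMD undefined", year, bee_taxon
            )
            continue
        mism = (grp["end_day"].astype(float) - est.wmd).abs()
        rows.append(
            pd.DataFrame(
                {
                    "nest_id": grp["nest_id"],
                    "bee_taxon": bee_taxon,
                    "season_year": int(year),
                    "mismatch_days": mism,
                    "brood_cells": grp["brood_cells"],
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["nest_id", "bee_taxon", "season_year", "mismatch_days", "brood_cells"]
        )
    return pd.concat(rows, ignore_index=True)


def population_mismatch_table(
    nests: pd.DataFrame, flowering: Mapping[int, PhenologyEstimate], bee_taxon: str
) -> pd.DataFrame:
    """Per-season population mismatch plus mean brood cells per nest."""
    sub = nests[nests["bee_taxon"] == bee_taxon]
    rows = []
    for year in sorted(flowering):
        rec = population_mismatch(sub, bee_taxon, flowering[year])
        if rec is None:
            continue
        grp = sub[sub["season_year"] == year]
        rows.append(
            {
                "bee_taxon": bee_taxon,
                "season_year": year,
                "nesting_wmd": nesting_wmd(sub, bee_taxon, year).wmd,
                "flowering_wmd": flowering[year].wmd,
                "mismatch_days": rec.mismatch_days,
                "n_nests": int(len(grp)),
                "mean_brood_cells": float(grp["brood_cells"].mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bee_taxon",
            "season_year",
            "nesting_wmd",
            "flowering_wmd",
            "mismatch_days",
            "n_nests",
            "mean_brood_cells",
        ],
    )
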
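"""Population growth rates from yearly brood-cell totals.

The yearly population size N_t of a species is the total number of brood
cells produced in all of its nests in season t.  The per-year growth rate
is lambda_t = N_{t+1} / N_t over consecutive seasons, and the average
growth rate is reported on the log scale,

    lambda_bar = mean_t ln(N_{t+1} / N_t),

the arithmetic mean of log ratios (the log of the geometric mean of the
lambda_t): lambda_bar > 0 means expected growth, < 0 expected decline.
Transitions in which either endpoint is zero or missing carry no usable
ratio and are skipped (and logged).

Uncertainty is quantified by a percentile bootstrap over nests: each
replicate resamples the species' nests with replacement — stratified
within season by default, preserving the per-season nest counts that the
year structure of lambda_bar depends on — recomputes lambda_bar, and the
95% interval is the 2.5% / 97.5% empirical quantiles over replicates.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedDemographyError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemographyResult:
    bee_taxon: str
    yearly_totals: dict
    lambda_series: dict  # {(t, t+1): lambda_t}
    lambda_bar: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_defined: int  # bootstrap replicates with a defined lambda_bar
    warnings: tuple = ()


def yearly_brood_totals(
    nests: pd.DataFrame, seasons: Sequence[int] | None = None
) -> dict[int, float]:
    """Total brood cells per season for one species' nest table.

    With ``seasons`` given, seasons without nests appear explicitly with
    N = 0 (they block the transitions that touch them).
    """
    if nests["brood_cells"].isna().any():
        raise ContractError("missing brood_cells; impute before demography")
    totals = nests.groupby("season_year")["brood_cells"].sum().to_dict()
    totals = {int(k): float(v) for k, v in totals.items()}
    if seasons is not None:
        totals = {int(s): totals.get(int(s), 0.0) for s in seasons}
    return totals


def mean_log_growth(yearly_totals: Mapping[int, float]) -> tuple[dict, float]:
    """lambda_t over usable consecutive transitions and their mean log.

    A transition t -> t+1 is usable when both seasons are present with
    N > 0.  Raises :class:`UndefinedDemographyError` when none is.
    """
    totals = {int(k): float(v) for k, v in yearly_totals.items()}
    series: dict[tuple[int, int], float] = {}
    for t in sorted(totals):
        n0, n1 = totals.get(t), totals.get(t + 1)
        if n1 is None:
            continue
        if n0 > 0 and n1 > 0:
            series[(t, t + 1)] = n1 / n0
        else:
            logger.warning("transition %s->%s skipped (zero total)", t, t + 1)
    if not series:
        raise UndefinedDemographyError("no usable consecutive transition")
    lambda_bar = float(np.mean(np.log(list(series.values()))))
    return series, lambda_bar


def _taxon_rng(seed: int, bee_taxon: str) -> np.random.Generator:
    # one reproducible stream per (seed, taxon); all replicates drawn from it
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(bee_taxon).encode())])
    )


def bootstrap_lambda_ci(
    nests: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    stratified: bool = True,
    bee_taxon: str = "",
    seasons: Sequence[int] | None = None,
) -> tuple[float, float, int]:
    """95% percentile bootstrap CI for lambda_bar.

    Nests are resampled with replacement; ``stratified`` (default) keeps
    each season's nest count fixed, the pooled alternative resamples the
    whole nest list.  Returns (ci_low, ci_high, number of replicates with
    a defined lambda_bar); fewer than 50% defined replicates triggers a
    warning.
    """
    cells = nests["brood_cells"].to_numpy(dtype=float)
    years = nests["season_year"].to_numpy(dtype=int)
    if np.isnan(cells).any():
        raise ContractError("missing brood_cells; impute before demography")
    rng = _taxon_rng(seed, bee_taxon)
    season_list = sorted(set(years) | set(int(s) for s in (seasons or [])))
    # replicate x season matrix of resampled totals
    totals = np.zeros((n_boot, len(season_list)))
    if stratified:
        for j, s in enumerate(season_list):
            vals = cells[years == s]
            if vals.size == 0:
                continue
            counts = rng.multinomial(vals.size, np.full(vals.size, 1 / vals.size), size=n_boot)
            totals[:, j] = counts @ vals
    else:
        n = cells.size
        counts = rng.multinomial(n, np.full(n, 1 / n), size=n_boot)
        for j, s in enumerate(season_list):
            mask = years == s
            totals[:, j] = counts[:, mask] @ cells[mask]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = totals[:, 1:] / totals[:, :-1]
        usable = (totals[:, 1:] > 0) & (totals[:, :-1] > 0)
        logs = np.where(usable, np.log(np.where(usable, ratios, 1.0)), np.nan)
    n_usable = usable.sum(axis=1)
    defined = n_usable > 0
    lam = np.nansum(logs, axis=1)[defined] / n_usable[defined]
    n_defined = int(defined.sum())
    if n_defined == 0:
        raise UndefinedDemographyError("no bootstrap replicate has a usable transition")
    if n_defined < 0.5 * n_boot:
        logger.warning(
            "%s: lambda_bar defined in only %d/%d bootstrap replicates",
            bee_taxon,
            n_defined,
            n_boot,
        )
    ci_low, ci_high = np.quantile(lam, [0.025, 0.975])
    return float(ci_low), float(ci_high), n_defined


def demography_result(
    nests: pd.DataFrame,
    bee_taxon: str,
    n_boot: int = 1000,
    seed: int = 0,
    stratified: bool = True,
    seasons: Sequence[int] | None = None,
) -> DemographyResult:
    """Point estimate plus bootstrap CI for one species."""
    sub = nests[nests["bee_taxon"] == bee_taxon] if "bee_taxon" in nests else nests
    totals = yearly_brood_totals(sub, seasons=seasons)
    series, lambda_bar = mean_log_growth(totals)
    ci_low, ci_high, n_defined = bootstrap_lambda_ci(
        sub,
        n_boot=n_boot,
        seed=seed,
        stratified=stratified,
        bee_taxon=bee_taxon,
        seasons=seasons,
    )
    warn = ()
    if n_defined < 0.5 * n_boot:
        warn = (f"lambda_bar defined in only {n_defined}/{n_boot} bootstrap replicates",)
    return DemographyResult(
        bee_taxon=bee_taxon,
        yearly_totals=totals,
        lambda_series=series,
        lambda_bar=lambda_bar,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        n_defined=n_defined,
        warnings=warn,
    )
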
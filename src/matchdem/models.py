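"""Mismatch-recruitment models.

Nest level: the number of brood cells per nest is regressed on that nest's
phenological mismatch with a linear mixed model whose random intercept is
the season (year), fitted by maximum likelihood so AIC is comparable
across mean structures.  Two forms are fitted per species —

* linear:       cells       = a + b * mismatch + u_year + e
* exponential:  ln(cells)   = a + b * mismatch + u_year + e

— and the lower-AIC form is selected (ties favour the exponential form).
For cross-species comparison, predictor and response can be standardized
(z-scored) before fitting, making the slope a unitless standardized
coefficient.

Population level: the yearly mean brood cells per nest is related to the
yearly population mismatch by Spearman's rank correlation, with the
analytic standard error sqrt((1 - rho^2) / (n - 2)).

Cross-species summary: the unweighted mean of the per-species coefficients
with a 95% percentile bootstrap interval obtained by resampling species
with replacement (wide by construction at five species).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CannotFitError, ContractError, InsufficientDataError

logger = logging.getLogger(__name__)

LINEAR = "linear"
EXPONENTIAL = "exponential"

MIN_NESTS = 10


@dataclass(frozen=True)
class MixedModelFit:
    bee_taxon: str
    form: str
    slope: float
    slope_se: float
    intercept: float
    aic: float
    n_obs: int
    n_years: int
    standardized: bool
    degenerate: bool = False

    @property
    def slope_ci(self) -> tuple[float, float]:
        """95% interval for the mismatch slope.

        Uses a t quantile with n_years - 1 degrees of freedom: with few
        year clusters the usual Wald z interval is anti-conservative, and
        a between-cluster df correction is the standard small-sample fix.
        """
        df = max(self.n_years - 1, 1)
        half = float(stats.t.ppf(0.975, df)) * self.slope_se
        return (self.slope - half, self.slope + half)


@dataclass(frozen=True)
class PopulationCorrelation:
    bee_taxon: str
    rho: float
    rho_se: float
    n_years: int
    degenerate: bool = False


@dataclass(frozen=True)
class CrossSpeciesSummary:
    mean_coefficient: float
    ci_low: float
    ci_high: float
    per_species: dict


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise CannotFitError("zero variance; cannot standardize")
    return (v - v.mean()) / sd


def fit_mismatch_model(
    data: pd.DataFrame,
    bee_taxon: str = "",
    form: str = EXPONENTIAL,
    standardized: bool = False,
    min_nests: int = MIN_NESTS,
) -> MixedModelFit:
    """Mixed model of brood cells (or their natural log) on mismatch days.

    ``data`` needs columns ``mismatch_days``, ``brood_cells`` and
    ``season_year``.  Year enters as a random intercept; estimation is by
    maximum likelihood.
    """
    if form not in (LINEAR, EXPONENTIAL):
        raise ContractError(f"unknown form {form!r}")
    sub = data.dropna(subset=["mismatch_days", "brood_cells"])
    n_years = sub["season_year"].nunique()
    if n_years < 2:
        raise InsufficientDataError(
            f"{bee_taxon}: need >= 2 seasons for a year random effect, got {n_years}"
        )
    if len(sub) < min_nests:
        raise InsufficientDataError(
            f"{bee_taxon}: need >= {min_nests} nests, got {len(sub)}"
        )
    x = sub["mismatch_days"].to_numpy(dtype=float)
    y = sub["brood_cells"].to_numpy(dtype=float)
    if form == EXPONENTIAL:
        if np.any(y < 1):
            raise ContractError("brood_cells < 1 under the exponential form")
        y = np.log(y)
    if np.ptp(x) == 0:
        raise CannotFitError(f"{bee_taxon}: zero variance in mismatch predictor")
    if np.ptp(y) == 0:
        logger.warning("%s: response constant across nests; degenerate fit", bee_taxon)
        return MixedModelFit(
            bee_taxon=bee_taxon,
            form=form,
            slope=0.0,
            slope_se=float("nan"),
            intercept=float(y[0]),
            aic=float("nan"),
            n_obs=int(len(sub)),
            n_years=int(n_years),
            standardized=standardized,
            degenerate=True,
        )
    if standardized:
        x, y = _zscore(x), _zscore(y)
    groups = sub["season_year"].to_numpy()
    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, exog, groups=groups).fit(reml=False)
            params = np.asarray(res.fe_params, dtype=float)
            bse = np.asarray(res.bse_fe, dtype=float)
            aic = float(res.aic)
        except (np.linalg.LinAlgError, ValueError):
            # near-singular random-effect problem (e.g. noiseless data):
            # collapse to the fixed-effect fit
            ols = sm.OLS(y, exog).fit()
            params = np.asarray(ols.params, dtype=float)
            bse = np.asarray(ols.bse, dtype=float)
            aic = float(ols.aic)
            logger.warning("%s: mixed fit degenerate; fixed-effects fallback", bee_taxon)
    if not np.all(np.isfinite(params)):
        raise CannotFitError(f"{bee_taxon}: mixed model failed to converge")
    return MixedModelFit(
        bee_taxon=bee_taxon,
        form=form,
        slope=float(params[1]),
        slope_se=float(bse[1]),
        intercept=float(params[0]),
        aic=aic,
        n_obs=int(len(sub)),
        n_years=int(n_years),
        standardized=standardized,
    )


def select_model(linear: MixedModelFit, exponential: MixedModelFit) -> MixedModelFit:
    """Return the lower-AIC fit; ties favour the exponential form."""
    if linear.form != LINEAR or exponential.form != EXPONENTIAL:
        raise ContractError("arguments must be (linear fit, exponential fit)")
    same = (
        linear.bee_taxon == exponential.bee_taxon
        and linear.n_obs == exponential.n_obs
        and linear.n_years == exponential.n_years
        and linear.standardized == exponential.standardized
    )
    if not same:
        raise ContractError("fits do not describe the same data")
    if not (np.isfinite(linear.aic) and np.isfinite(exponential.aic)):
        raise ContractError("cannot compare degenerate fits by AIC")
    if linear.aic < exponential.aic - 1e-6:
        return linear
    return exponential


def population_spearman(data: pd.DataFrame, bee_taxon: str = "") -> PopulationCorrelation:
    """Spearman correlation of yearly mean cells per nest with mismatch.

    ``data`` needs one row per season with ``mismatch_days`` and
    ``mean_brood_cells``.  Requires >= 4 seasons.  A constant variable
    makes ranks degenerate; rho is then reported as 0 with a flag.
    """
    sub = data.dropna(subset=["mismatch_days", "mean_brood_cells"])
    n = len(sub)
    if n < 4:
        raise InsufficientDataError(f"{bee_taxon}: need >= 4 seasons, got {n}")
    x = sub["mismatch_days"].to_numpy(dtype=float)
    y = sub["mean_brood_cells"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("%s: constant variable; Spearman rho undefined", bee_taxon)
        return PopulationCorrelation(bee_taxon, 0.0, float("nan"), n, degenerate=True)
    rho = float(stats.spearmanr(x, y).statistic)
    rho_se = float(np.sqrt((1 - rho**2) / (n - 2)))
    return PopulationCorrelation(bee_taxon, rho, rho_se, n)


def cross_species_mean(
    per_species: dict, n_boot: int = 1000, seed: int = 0
) -> CrossSpeciesSummary:
    """Mean coefficient across species with a percentile bootstrap CI.

    ``per_species`` maps bee taxon to either a bare coefficient or any
    object with a ``slope`` (or ``rho``) attribute.
    """
    def coef(v):
        for attr in ("slope", "rho"):
            if hasattr(v, attr):
                return float(getattr(v, attr))
        return float(v)

    taxa = sorted(per_species)
    if len(taxa) < 3:
        raise InsufficientDataError(f"need >= 3 species, got {len(taxa)}")
    values = np.asarray([coef(per_species[t]) for t in taxa], dtype=float)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(b"cross_species")])
    )
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boots = values[idx].mean(axis=1)
    ci_low, ci_high = np.quantile(boots, [0.025, 0.975])
    return CrossSpeciesSummary(
        mean_coefficient=float(values.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        per_species={t: coef(per_species[t]) for t in taxa},
    )
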
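"""Brood-cell counts per nest, imputed from cavity length where needed.

Some cavity-nesting species do not leave countable brood cells (bare eggs
in a pollen mass) or emerge before cells can be counted.  For those
species the number of cells is estimated from the length of the occupied
trap cavity: an ordinary least-squares regression of cell count on cavity
length is fitted on the subset of nests where both were recorded, and its
prediction — rounded to the nearest integer and floored at 1, since a
completed nest holds at least one cell — fills the missing counts.  Direct
counts are never overwritten, and imputed values are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CannotFitError, ContractError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellsLengthModel:
    """Per-species linear model: brood_cells ~ intercept + slope * cavity_length."""

    bee_taxon: str
    intercept: float
    slope: float  # cells per mm
    n_train: int
    r_squared: float

    def predict(self, cavity_length: float) -> float:
        return self.intercept + self.slope * float(cavity_length)


def fit_cells_vs_length(train: pd.DataFrame, bee_taxon: str = "") -> CellsLengthModel:
    """OLS fit of brood cells on occupied cavity length.

    Requires at least 3 training nests with both quantities present and
    non-degenerate lengths.  A non-positive slope is biologically
    implausible (longer cavities hold more cells) and triggers a warning.
    """
    sub = train.dropna(subset=["brood_cells", "cavity_length"])
    if len(sub) < 3:
        raise CannotFitError(
            f"{bee_taxon or 'taxon'}: need >= 3 nests with both brood_cells and "
            f"cavity_length, got {len(sub)}"
        )
    x = sub["cavity_length"].to_numpy(dtype=float)
    y = sub["brood_cells"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise CannotFitError(f"{bee_taxon or 'taxon'}: zero variance in cavity_length")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    model = CellsLengthModel(
        bee_taxon=bee_taxon,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        n_train=int(len(sub)),
        r_squared=float(res.rsquared),
    )
    if model.slope <= 0:
        logger.warning(
            "%s: cells-vs-length slope %.4f is not positive", bee_taxon, model.slope
        )
    return model


def impute_brood_cells(nest, model: CellsLengthModel) -> int:
    """Predicted cell count for one nest, rounded and floored at 1."""
    length = nest["cavity_length"] if not np.isscalar(nest) else nest
    if length is None or (isinstance(length, float) and np.isnan(length)):
        raise ContractError("cavity_length missing; cannot impute")
    raw = model.predict(length)
    cells = int(round(raw))
    if cells < 1:
        logger.warning(
            "%s: predicted %.2f cells for length %.1f mm; clamped to 1",
            model.bee_taxon,
            raw,
            float(length),
        )
        cells = 1
    return cells


def impute_cells(
    nests: pd.DataFrame, length_measured_taxa=None
) -> tuple[pd.DataFrame, dict[str, CellsLengthModel]]:
    """Fill missing brood-cell counts for the length-measured species.

    Returns the augmented table (with an ``estimated`` boolean column) and
    the fitted per-species models.  ``length_measured_taxa`` limits which
    species are imputed; by default every species with at least one missing
    count is considered.
    """
    out = nests.copy()
    out["estimated"] = False
    missing = out["brood_cells"].isna()
    taxa = (
        set(length_measured_taxa)
        if length_measured_taxa is not None
        else set(out.loc[missing, "bee_taxon"])
    )
    models: dict[str, CellsLengthModel] = {}
    for taxon in sorted(taxa):
        rows = out["bee_taxon"] == taxon
        if not (rows & missing).any():
            continue
        model = fit_cells_vs_length(out[rows], taxon)
        models[taxon] = model
        idx = out.index[rows & missing]
        out.loc[idx, "brood_cells"] = [
            float(impute_brood_cells(out.loc[i], model)) for i in idx
        ]
        out.loc[idx, "estimated"] = True
        logger.info("%s: imputed %d of %d nests", taxon, len(idx), int(rows.sum()))
    still = out["brood_cells"].isna()
    if still.any():
        raise ContractError(
            f"{int(still.sum())} nests remain without brood_cells after imputation"
        )
    return out, models
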
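"""Diet-breadth (generalization) scores from nest pollen contents.

Each nest's pollen grain counts are first normalized to proportions, which
removes the effect of how many grains happened to be counted for that nest.
These per-nest proportions are then summed across all examined nests of a
bee species, giving each plant taxon an abundance between 0 and the number
of nests, and Shannon's diversity index

    H = -sum_i p_i ln p_i

is computed on those summed abundances.  H = 0 for a strict monolectic
specialist and grows toward ln(k) as the diet spreads evenly over k plant
taxa; it is the generalization axis against which mismatch effects are
compared across species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

__all__ = [
    "GeneralizationScore",
    "nest_pollen_proportions",
    "species_abundance_across_nests",
    "shannon_index",
    "generalization_scores",
]


@dataclass(frozen=True)
class GeneralizationScore:
    bee_taxon: str
    shannon_h: float
    n_nests: int
    species_abundances: dict


def nest_pollen_proportions(samples) -> dict[str, float]:
    """Normalize one nest's grain counts to proportions summing to 1.

    ``samples`` is either a ``{plant_taxon: grain_count}`` mapping or a
    DataFrame slice with ``plant_taxon`` and ``grain_count`` columns.
    """
    if isinstance(samples, pd.DataFrame):
        counts = dict(zip(samples["plant_taxon"], samples["grain_count"].astype(float)))
        nest = str(samples["nest_id"].iloc[0]) if "nest_id" in samples and len(samples) else "?"
    else:
        counts = {t: float(c) for t, c in dict(samples).items()}
        nest = "?"
    if any(c < 0 for c in counts.values()):
        raise ContractError("negative grain count")
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError(f"nest {nest}: all pollen grain counts are zero")
    return {t: c / total for t, c in counts.items() if c > 0}


def species_abundance_across_nests(per_nest: Iterable[Mapping[str, float]]) -> dict[str, float]:
    """Sum per-nest proportions into population-level plant abundances.

    The totals over all plant taxa equal the number of nests, so every nest
    contributes equally regardless of how many grains it yielded.
    """
    per_nest = list(per_nest)
    if not per_nest:
        raise ValidationError("no nests provided")
    out: dict[str, float] = {}
    for proportions in per_nest:
        for taxon, p in proportions.items():
            out[taxon] = out.get(taxon, 0.0) + float(p)
    return out


def shannon_index(abundances: Mapping[str, float], base: float | None = None) -> float:
    """Shannon diversity of an abundance vector (natural log by default)."""
    values = np.asarray([float(v) for v in abundances.values()], dtype=float)
    if np.any(values < 0):
        raise ContractError("negative abundance")
    total = values.sum()
    if total <= 0:
        raise ValidationError("all abundances are zero")
    p = values[values > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    # guard against -0.0 from a single-taxon vector
    return abs(h) if h == 0 else h


def generalization_scores(
    pollen: pd.DataFrame, nests: pd.DataFrame, base: float | None = None
) -> dict[str, GeneralizationScore]:
    """Per-bee-species Shannon generalization from the pollen table.

    Pollen samples are attributed to bee species through the nest table;
    samples whose nest_id has no nest record are ignored with a
    :class:`ValidationError` only if *all* samples are orphaned.
    """
    taxon_of = dict(zip(nests["nest_id"], nests["bee_taxon"]))
    merged = pollen[pollen["nest_id"].isin(taxon_of)]
    if merged.empty:
        raise ValidationError("no pollen sample matches a recorded nest")
    out: dict[str, GeneralizationScore] = {}
    bees = merged["nest_id"].map(taxon_of)
    for bee_taxon, grp in merged.groupby(bees):
        per_nest = [
            nest_pollen_proportions(nest_grp)
            for _, nest_grp in grp.groupby("nest_id")
            if nest_grp["grain_count"].sum() > 0
        ]
        abundances = species_abundance_across_nests(per_nest)
        out[str(bee_taxon)] = GeneralizationScore(
            bee_taxon=str(bee_taxon),
            shannon_h=shannon_index(abundances, base=base),
            n_nests=len(per_nest),
            species_abundances=abundances,
        )
    return out
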
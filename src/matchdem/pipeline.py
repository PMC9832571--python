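"""End-to-end orchestration: data -> scores -> mismatch -> models -> demography.

``run_pipeline`` either ingests the three field tables or simulates them
from a scenario config, then runs every analysis stage and writes one CSV
per stage plus a JSON run manifest recording the config digest, seed,
output files with their SHA-256 digests, per-species season exclusions,
imputation counts and all warnings raised along the way.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brood import impute_cells
from .demography import demography_result
from .errors import ConfigurationError, InsufficientDataError, MatchdemError
from .generalization import generalization_scores
from .io_formats import (
    aggregate_flowers,
    read_floral_surveys,
    read_nests,
    read_pollen,
    write_floral_surveys,
    write_nests,
    write_pollen,
)
from .models import (
    EXPONENTIAL,
    LINEAR,
    cross_species_mean,
    fit_mismatch_model,
    population_spearman,
    select_model,
)
from .phenology import (
    flowering_wmd_by_season,
    identify_main_resources,
    nest_mismatch_table,
    population_mismatch_table,
)
from .simulate import ScenarioConfig, default_scenario, generate_dataset, scenario_from_yaml

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    outputs: dict = field(default_factory=dict)  # stage -> [paths]
    file_digests: dict = field(default_factory=dict)
    excluded_seasons: dict = field(default_factory=dict)
    imputed_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    versions: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record):
        self.records.append(self.format(record))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_digest(config: ScenarioConfig | None) -> str:
    if config is None:
        return "ingested-data"
    import dataclasses

    payload = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    out_dir,
    config: ScenarioConfig | str | Path | None = None,
    inputs: dict | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    dialect: dict | None = None,
    stratified_bootstrap: bool = True,
    plots: bool = False,
) -> RunManifest:
    """Run every stage and return the manifest.

    Either ``inputs`` (paths for ``flowers``, ``nests``, ``pollen``) or a
    scenario ``config`` (object, YAML path, or None for the default
    scenario) must describe where data come from; ingestion wins when both
    are given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("matchdem").addHandler(collector)
    try:
        return _run(out, config, inputs, seed, n_boot, dialect, stratified_bootstrap, plots, collector)
    finally:
        logging.getLogger("matchdem").removeHandler(collector)


def _run(out, config, inputs, seed, n_boot, dialect, stratified, plots, collector):
    if isinstance(config, (str, Path)):
        config = scenario_from_yaml(config)

    # --- stage 1: data -----------------------------------------------------
    if inputs is not None:
        for key in ("flowers", "nests", "pollen"):
            if key not in inputs:
                raise ConfigurationError(
                    f"input table {key!r} not configured and simulation not requested"
                )
        flowers = read_floral_surveys(inputs["flowers"], dialect)
        nests = read_nests(inputs["nests"], dialect)
        pollen = read_pollen(inputs["pollen"], dialect)
        config_for_digest = None
    else:
        if config is None:
            config = default_scenario(seed=seed)
        flowers, nests, pollen = generate_dataset(config, seed=seed)
        config_for_digest = config
    manifest = RunManifest(
        config_digest=_config_digest(config_for_digest),
        seed=int(seed),
        versions={"matchdem": __version__},
    )
    write_floral_surveys(flowers, out / "flowers.csv")
    write_nests(nests, out / "nests.csv")
    write_pollen(pollen, out / "pollen.csv")
    manifest.outputs["data"] = [str(out / f) for f in ("flowers.csv", "nests.csv", "pollen.csv")]

    flowers_pooled = aggregate_flowers(flowers)
    taxa = sorted(nests["bee_taxon"].unique())
    seasons = sorted(nests["season_year"].unique())

    # --- stage 2: generalization ------------------------------------------
    scores = generalization_scores(pollen, nests)
    gen_df = pd.DataFrame(
        [
            {"bee_taxon": t, "shannon_h": s.shannon_h, "n_nests": s.n_nests}
            for t, s in sorted(scores.items())
        ]
    )
    gen_df.to_csv(out / "generalization.csv", index=False)
    manifest.outputs["generalization"] = [str(out / "generalization.csv")]

    # --- stage 3: brood-cell imputation ------------------------------------
    nests_full, cell_models = impute_cells(nests)
    write_nests(nests_full, out / "nests_imputed.csv")
    manifest.outputs["imputation"] = [str(out / "nests_imputed.csv")]
    for taxon in taxa:
        rows = nests_full["bee_taxon"] == taxon
        manifest.imputed_counts[taxon] = int(nests_full.loc[rows, "estimated"].sum())

    # --- stage 4: phenology and mismatch -----------------------------------
    nest_tables, pop_tables = {}, {}
    for taxon in taxa:
        score = scores.get(taxon)
        if score is None:
            manifest.warnings.append(f"{taxon}: no pollen data; skipped")
            continue
        resources = identify_main_resources(score.species_abundances, taxon)
        wmds = flowering_wmd_by_season(flowers_pooled, resources)
        nest_tables[taxon] = nest_mismatch_table(nests_full, wmds, taxon)
        pop_tables[taxon] = population_mismatch_table(nests_full, wmds, taxon)
        observed = set(pop_tables[taxon]["season_year"])
        manifest.excluded_seasons[taxon] = sorted(set(seasons) - observed)
    pd.concat(nest_tables.values(), ignore_index=True).to_csv(
        out / "nest_mismatch.csv", index=False
    )
    pd.concat(pop_tables.values(), ignore_index=True).to_csv(
        out / "population_phenology.csv", index=False
    )
    manifest.outputs["phenology"] = [
        str(out / "nest_mismatch.csv"),
        str(out / "population_phenology.csv"),
    ]

    # --- stage 5: mismatch-recruitment models -------------------------------
    model_rows, std_slopes, rhos = [], {}, {}
    for taxon in taxa:
        data = nest_tables.get(taxon)
        if data is None or data.empty:
            continue
        try:
            lin = fit_mismatch_model(data, taxon, LINEAR)
            expo = fit_mismatch_model(data, taxon, EXPONENTIAL)
            best = select_model(lin, expo)
            std = fit_mismatch_model(data, taxon, EXPONENTIAL, standardized=True)
        except MatchdemError as exc:
            manifest.warnings.append(f"{taxon}: model skipped ({exc})")
            continue
        std_slopes[taxon] = std
        model_rows.append(
            {
                "bee_taxon": taxon,
                "selected_form": best.form,
                "aic_linear": lin.aic,
                "aic_exponential": expo.aic,
                "slope": best.slope,
                "slope_se": best.slope_se,
                "std_slope": std.slope,
                "std_slope_se": std.slope_se,
                "n_obs": best.n_obs,
                "n_years": best.n_years,
                "shannon_h": scores[taxon].shannon_h,
            }
        )
        try:
            rhos[taxon] = population_spearman(pop_tables[taxon], taxon)
        except InsufficientDataError as exc:
            manifest.warnings.append(f"{taxon}: Spearman skipped ({exc})")
    pd.DataFrame(model_rows).to_csv(out / "models.csv", index=False)
    summary = {}
    if len(std_slopes) >= 3:
        cs = cross_species_mean(std_slopes, n_boot=n_boot, seed=seed)
        summary["standardized_slope"] = cs.__dict__
    if len(rhos) >= 3:
        cr = cross_species_mean(rhos, n_boot=n_boot, seed=seed)
        summary["spearman_rho"] = cr.__dict__
    with open(out / "cross_species.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    manifest.outputs["models"] = [str(out / "models.csv"), str(out / "cross_species.json")]

    # --- stage 6: demography ------------------------------------------------
    demo_rows = []
    for taxon in taxa:
        try:
            res = demography_result(
                nests_full,
                taxon,
                n_boot=n_boot,
                seed=seed,
                stratified=stratified,
                seasons=seasons,
            )
        except MatchdemError as exc:
            manifest.warnings.append(f"{taxon}: demography skipped ({exc})")
            continue
        demo_rows.append(
            {
                "bee_taxon": taxon,
                "lambda_bar": res.lambda_bar,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_transitions": len(res.lambda_series),
                "n_boot": res.n_boot,
            }
        )
        manifest.warnings.extend(f"{taxon}: {w}" for w in res.warnings)
    pd.DataFrame(demo_rows).to_csv(out / "demography.csv", index=False)
    manifest.outputs["demography"] = [str(out / "demography.csv")]

    if plots:
        from .plots import mismatch_panels

        fig_path = out / "mismatch_panels.png"
        mismatch_panels(nest_tables, fig_path)
        manifest.outputs["figures"] = [str(fig_path)]

    manifest.warnings.extend(collector.records)
    for paths in manifest.outputs.values():
        for p in paths:
            manifest.file_digests[p] = _sha256(Path(p))
    manifest.to_json(out / "manifest.json")
    return manifest
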
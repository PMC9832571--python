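"""Synthetic field data with the statistical structure the analysis assumes.

The generator emulates a multi-year trap-nest study: two sites surveyed
weekly over a 9-season span, a plant community with unimodal (Gaussian)
seasonal flowering curves whose peaks shift from year to year, and five
bee species spanning a specialization gradient.  Nest end-of-construction
days track each species' resource flowering with a species-level yearly
offset plus nest-level spread, so nesting-flowering mismatch varies both
within and among years.  Brood cells per nest decline exponentially with
that mismatch:

    cells = max(1, round(exp(ln(mean_cells) + effect * mismatch
                             + year_effect + noise)))

with the decline strength (``mismatch_effect``, per day, <= 0) weakening
along the generalization gradient.  Pollen compositions are Dirichlet
draws around each species' resource preference vector, counted
multinomially — tight single-resource compositions for specialists, flat
ones for generalists — and sampled, as in a field pollen study, only for
the first few seasons.

All outputs are plain DataFrames in the canonical table schemas and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .phenology import flowering_wmd_by_season, identify_main_resources


@dataclass
class PlantSpecies:
    taxon: str
    peak_day: float  # day of season of the long-term mean flowering peak
    peak_sd: float  # width (sd, days) of the Gaussian flowering curve
    peak_abundance: float  # flowers/plot at the peak, summed over plots
    year_shift_sd: float = 6.0  # sd (days) of yearly peak shifts


@dataclass
class BeeSpecies:
    taxon: str
    preferences: dict  # plant_taxon -> relative pollen-use weight
    dirichlet_conc: float = 20.0  # concentration of per-nest compositions
    mismatch_effect: float = 0.0  # per-day effect on ln(brood cells), <= 0
    mean_cells: float = 8.0  # brood cells at zero mismatch
    nests_per_year: int = 10  # Poisson mean of nests per season
    nesting_spread: float = 15.0  # sd (days) of nest end days within a year
    length_measured: bool = False  # cells imputed from cavity length


@dataclass
class ScenarioConfig:
    bee_species: list
    plant_species: list
    n_years: int = 9
    start_year: int = 2006
    n_sites: int = 2
    plots_per_site: int = 2
    survey_interval: int = 7
    season_length: int = 180
    resource_threshold: float = 0.85
    pollen_years: int = 3  # pollen sampled in the first k seasons
    pollen_grains: float = 300.0  # mean grains counted per nest
    pollen_pref_floor: float = 0.002  # Dirichlet floor for unused plants
    nest_year_offset_sd: float = 6.0  # sd (days) of the shared yearly nesting offsets
    cell_noise_sd: float = 0.12  # residual sd on ln(cells)
    cell_year_sd: float = 0.06  # sd of yearly random effects on ln(cells)
    cavity_intercept: float = 10.0  # mm of cavity at zero cells
    cavity_slope: float = 9.0  # mm of cavity per brood cell
    cavity_noise_sd: float = 4.0  # mm
    mask_fraction: float = 0.6  # share of length-measured nests lacking counts
    seed: int = 0

    def __post_init__(self):
        self.bee_species = [
            b if isinstance(b, BeeSpecies) else BeeSpecies(**b) for b in self.bee_species
        ]
        self.plant_species = [
            p if isinstance(p, PlantSpecies) else PlantSpecies(**p)
            for p in self.plant_species
        ]
        if self.survey_interval < 1:
            raise ConfigurationError("survey_interval must be >= 1")
        for p in self.plant_species:
            if p.peak_sd <= 0 or p.peak_abundance <= 0:
                raise ConfigurationError(f"{p.taxon}: non-positive curve parameters")
        for b in self.bee_species:
            if b.nesting_spread <= 0 or b.mean_cells <= 1:
                raise ConfigurationError(f"{b.taxon}: invalid bee parameters")

    @property
    def seasons(self) -> list:
        return list(range(self.start_year, self.start_year + self.n_years))


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The default 9-season, 2-site, 5-species study scenario.

    The five bees span a specialization gradient (near-monolectic to fully
    polylectic) with a matched gradient of mismatch effects on log brood
    cells, strongest for the specialist and essentially nil for the
    generalist; per-species nest totals over the 9 seasons roughly follow
    a 45/62/75/151/433 abundance ladder, the generalist being the most
    abundant.
    """
    plants = [
        PlantSpecies("plant_P1", 75.0, 12.0, 400.0),
        PlantSpecies("plant_P2", 85.0, 14.0, 300.0),
        PlantSpecies("plant_P3", 95.0, 13.0, 250.0),
        PlantSpecies("plant_P4", 65.0, 10.0, 150.0),
        PlantSpecies("plant_P5", 105.0, 15.0, 120.0),
        PlantSpecies("plant_P6", 55.0, 9.0, 80.0),
        PlantSpecies("plant_P7", 115.0, 12.0, 60.0),
        PlantSpecies("plant_P8", 90.0, 20.0, 50.0),
    ]
    bees = [
        BeeSpecies(
            "bee_B1_specialist",
            {"plant_P1": 0.92, "plant_P2": 0.05, "plant_P3": 0.02, "plant_P4": 0.01},
            mismatch_effect=-0.065,
            mean_cells=14.0,
            nests_per_year=5,
        ),
        BeeSpecies(
            "bee_B2",
            {"plant_P1": 0.64, "plant_P2": 0.26, "plant_P3": 0.07, "plant_P4": 0.03},
            mismatch_effect=-0.020,
            mean_cells=9.0,
            nests_per_year=7,
            length_measured=True,
        ),
        BeeSpecies(
            "bee_B3",
            {
                "plant_P1": 0.44,
                "plant_P2": 0.29,
                "plant_P3": 0.17,
                "plant_P4": 0.06,
                "plant_P5": 0.04,
            },
            mismatch_effect=-0.0098,
            mean_cells=8.0,
            nests_per_year=8,
            length_measured=True,
        ),
        BeeSpecies(
            "bee_B4",
            {
                "plant_P1": 0.30,
                "plant_P2": 0.22,
                "plant_P3": 0.17,
                "plant_P4": 0.13,
                "plant_P5": 0.09,
                "plant_P6": 0.05,
                "plant_P7": 0.03,
                "plant_P8": 0.01,
            },
            mismatch_effect=-0.0032,
            mean_cells=7.0,
            nests_per_year=17,
        ),
        BeeSpecies(
            "bee_B5_generalist",
            {f"plant_P{i}": 0.125 for i in range(1, 9)},
            mismatch_effect=-0.0003,
            mean_cells=6.0,
            nests_per_year=48,
        ),
    ]
    return ScenarioConfig(bee_species=bees, plant_species=plants, seed=seed)


def single_species_scenario(
    mismatch_effect: float = -0.03,
    nests_per_year: int = 150,
    mean_cells: float = 8.0,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """One specialist species on the default plant community.

    Convenient for parameter-recovery studies: the species forages almost
    exclusively on the dominant plant and its nests per season are fixed
    at a large, configurable number.
    """
    base = default_scenario(seed=seed)
    bee = BeeSpecies(
        "bee_focal",
        {"plant_P1": 0.92, "plant_P2": 0.05, "plant_P3": 0.02, "plant_P4": 0.01},
        mismatch_effect=mismatch_effect,
        mean_cells=mean_cells,
        nests_per_year=nests_per_year,
    )
    return ScenarioConfig(
        bee_species=[bee], plant_species=base.plant_species, seed=seed, **overrides
    )


def expected_pollen_composition(config: ScenarioConfig, bee: BeeSpecies) -> dict:
    """Expected observed pollen composition: preferences plus the Dirichlet floor."""
    plant_taxa = [p.taxon for p in config.plant_species]
    raw = {t: bee.preferences.get(t, 0.0) + config.pollen_pref_floor for t in plant_taxa}
    total = sum(raw.values())
    return {t: v / total for t, v in raw.items()}


def true_resource_sets(config: ScenarioConfig) -> dict:
    """Generator-truth main-resource sets from the expected pollen composition."""
    return {
        b.taxon: identify_main_resources(
            expected_pollen_composition(config, b),
            b.taxon,
            threshold=config.resource_threshold,
        )
        for b in config.bee_species
    }


def generate_flowering(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Weekly floral-survey table.

    Each plant's curve is a Gaussian in day-of-season whose peak is offset
    every year by a normal deviate (sd ``year_shift_sd``); expected counts
    are split evenly over sites and plots and rounded to integers, so with
    a zero shift sd the curves repeat identically every year.
    """
    days = np.arange(0, config.season_length + 1, config.survey_interval)
    n_units = config.n_sites * config.plots_per_site
    rows = []
    for plant in config.plant_species:
        shifts = rng.normal(0.0, plant.year_shift_sd, size=config.n_years)
        for iy, year in enumerate(config.seasons):
            peak = plant.peak_day + shifts[iy]
            mean = (plant.peak_abundance / n_units) * np.exp(
                -0.5 * ((days - peak) / plant.peak_sd) ** 2
            )
            counts = np.rint(mean).astype(int)
            for i_site in range(config.n_sites):
                site = f"site_{i_site + 1}"
                for i_plot in range(config.plots_per_site):
                    unit = f"{site}_plot_{i_plot + 1}"
                    keep = counts > 0
                    rows.append(
                        pd.DataFrame(
                            {
                                "season_year": year,
                                "day": days[keep],
                                "site": site,
                                "unit": unit,
                                "plant_taxon": plant.taxon,
                                "flower_count": counts[keep].astype(float),
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)


def generate_nests(
    config: ScenarioConfig, flowering: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Nest-record table conditioned on the generated flowering.

    Nest end days are normal around each season's resource flowering WMD
    plus a species-year offset; brood cells decline exponentially with the
    realized mismatch.  For length-measured species every nest carries a
    cavity length proportional to its cells, and a ``mask_fraction`` share
    of their cell counts is masked for downstream imputation.
    """
    resources = true_resource_sets(config)
    rows = []
    # one climate-driven nesting offset per season, shared by all species:
    # an early or late spring advances or delays every bee together
    year_offsets = rng.normal(0.0, config.nest_year_offset_sd, size=config.n_years)
    for bee in config.bee_species:
        wmds = flowering_wmd_by_season(flowering, resources[bee.taxon])
        cell_year = rng.normal(0.0, config.cell_year_sd, size=config.n_years)
        for iy, year in enumerate(config.seasons):
            if year not in wmds:
                continue
            wmd = wmds[year].wmd
            n = int(rng.poisson(bee.nests_per_year))
            if n == 0:
                continue
            end = np.rint(
                rng.normal(wmd + year_offsets[iy], bee.nesting_spread, size=n)
            )
            end = np.clip(end, 0, config.season_length).astype(int)
            mism = np.abs(end - wmd)
            ln_cells = (
                np.log(bee.mean_cells)
                + bee.mismatch_effect * mism
                + cell_year[iy]
                + rng.normal(0.0, config.cell_noise_sd, size=n)
            )
            cells = np.maximum(1, np.rint(np.exp(ln_cells))).astype(float)
            cavity = np.full(n, np.nan)
            observed = cells.copy()
            if bee.length_measured:
                cavity = (
                    config.cavity_intercept
                    + config.cavity_slope * cells
                    + rng.normal(0.0, config.cavity_noise_sd, size=n)
                )
                cavity = np.clip(cavity, 1.0, None)
                masked = rng.random(n) < config.mask_fraction
                observed[masked] = np.nan
            sites = np.array(
                [f"site_{1 + (i % config.n_sites)}" for i in range(n)]
            )
            rows.append(
                pd.DataFrame(
                    {
                        "nest_id": [
                            f"{bee.taxon}-{year}-{i:03d}" for i in range(n)
                        ],
                        "bee_taxon": bee.taxon,
                        "site": sites,
                        "season_year": year,
                        "end_day": end,
                        "brood_cells": observed,
                        "cavity_length": cavity,
                        "true_cells": cells,
                    }
                )
            )
    nests = pd.concat(rows, ignore_index=True)
    return nests


def generate_pollen(
    config: ScenarioConfig, nests: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Pollen-sample table for nests from the pollen-study seasons.

    One extracted cell per nest: a Dirichlet composition around the
    species' preferences (concentration ``dirichlet_conc``) counted
    multinomially with a Poisson total around ``pollen_grains``.
    """
    plant_taxa = [p.taxon for p in config.plant_species]
    by_taxon = {b.taxon: b for b in config.bee_species}
    cutoff = config.start_year + config.pollen_years
    sampled = nests[nests["season_year"] < cutoff]
    rows = []
    for _, nest in sampled.iterrows():
        bee = by_taxon[nest["bee_taxon"]]
        comp_exp = expected_pollen_composition(config, bee)
        alpha = np.array([bee.dirichlet_conc * comp_exp[t] for t in plant_taxa])
        comp = rng.dirichlet(alpha)
        total = max(1, int(rng.poisson(config.pollen_grains)))
        counts = rng.multinomial(total, comp)
        keep = counts > 0
        rows.append(
            pd.DataFrame(
                {
                    "nest_id": nest["nest_id"],
                    "plant_taxon": np.asarray(plant_taxa)[keep],
                    "grain_count": counts[keep],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_dataset(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (flowers, nests, pollen) reproducibly from one seed."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    flowers = generate_flowering(config, rng)
    nests = generate_nests(config, flowers, rng)
    pollen = generate_pollen(config, nests, rng)
    return flowers, nests, pollen


def generate_growth_nests(
    n_years: int = 9,
    nests_per_year: int = 60,
    log_growth: float = 0.2,
    mean_cells: float = 6.0,
    start_year: int = 2006,
    seed: int = 0,
    bee_taxon: str = "bee_growth",
) -> pd.DataFrame:
    """Nest table for a population with known per-year log growth.

    Cells per nest are Poisson with a mean growing as exp(log_growth * t)
    while the number of nests stays fixed, so the expected yearly totals
    grow at exactly ``log_growth`` on the log scale.  Used for calibration
    studies of the demography bootstrap.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    rows = []
    for t in range(n_years):
        mu = mean_cells * np.exp(log_growth * t)
        cells = np.maximum(1, rng.poisson(mu, size=nests_per_year)).astype(float)
        year = start_year + t
        rows.append(
            pd.DataFrame(
                {
                    "nest_id": [f"{bee_taxon}-{year}-{i:03d}" for i in range(nests_per_year)],
                    "bee_taxon": bee_taxon,
                    "site": "site_1",
                    "season_year": year,
                    "end_day": 80,
                    "brood_cells": cells,
                    "cavity_length": np.nan,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _asdict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def scenario_to_yaml(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_asdict(config), fh, sort_keys=False)


def scenario_from_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "bee_species" not in raw:
        raise ConfigurationError(f"{path}: not a scenario config")
    try:
        return ScenarioConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc
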
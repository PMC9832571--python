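import math

import numpy as np
import pandas as pd
import pytest

from matchdem.errors import ConfigurationError
from matchdem.generalization import generalization_scores
from matchdem.phenology import weighted_mean_date
from matchdem.simulate import (
    BeeSpecies,
    PlantSpecies,
    ScenarioConfig,
    default_scenario,
    generate_dataset,
    generate_flowering,
    generate_growth_nests,
    generate_nests,
    scenario_from_yaml,
    scenario_to_yaml,
    true_resource_sets,
)


def _tiny_config(**overrides):
    plants = [PlantSpecies("A", 80.0, 12.0, 200.0, year_shift_sd=overrides.pop("shift", 5.0))]
    bees = [
        BeeSpecies(
            "bee",
            {"A": 1.0},
            mismatch_effect=overrides.pop("effect", -0.02),
            mean_cells=8.0,
            nests_per_year=overrides.pop("nests", 20),
            nesting_spread=overrides.pop("spread", 10.0),
        )
    ]
    return ScenarioConfig(bee_species=bees, plant_species=plants, n_years=4, **overrides)


class TestFlowering:
    def test_zero_shift_repeats_curves_identically(self):
        cfg = _tiny_config(shift=0.0)
        rng = np.random.default_rng(0)
        flowers = generate_flowering(cfg, rng)
        by_year = {
            y: grp.groupby("day")["flower_count"].sum()
            for y, grp in flowers.groupby("season_year")
        }
        years = sorted(by_year)
        for y in years[1:]:
            pd.testing.assert_series_equal(by_year[years[0]], by_year[y])

    def test_wmd_of_symmetric_curve_near_peak(self):
        cfg = _tiny_config(shift=0.0)
        flowers = generate_flowering(cfg, np.random.default_rng(1))
        daily = flowers[flowers["season_year"] == 2006].groupby("day")["flower_count"].sum()
        wmd = weighted_mean_date(daily.index.to_numpy(), daily.to_numpy())
        assert abs(wmd - 80.0) <= cfg.survey_interval / 2

    def test_doubling_abundance_leaves_wmd_unchanged(self):
        cfg = _tiny_config(shift=0.0)
        flowers = generate_flowering(cfg, np.random.default_rng(2))
        cfg2 = _tiny_config(shift=0.0)
        cfg2.plant_species[0].peak_abundance *= 2
        flowers2 = generate_flowering(cfg2, np.random.default_rng(2))
        d1 = flowers.groupby("day")["flower_count"].sum()
        d2 = flowers2.groupby("day")["flower_count"].sum()
        w1 = weighted_mean_date(d1.index.to_numpy(), d1.to_numpy())
        w2 = weighted_mean_date(d2.index.to_numpy(), d2.to_numpy())
        assert w2 == pytest.approx(w1, abs=0.2)


class TestNests:
    def test_degenerate_spread_and_offsets_pin_nests_to_wmd(self):
        cfg = _tiny_config(spread=1e-9)
        cfg.nest_year_offset_sd = 0.0
        rng = np.random.default_rng(3)
        flowers = generate_flowering(cfg, rng)
        nests = generate_nests(cfg, flowers, rng)
        from matchdem.phenology import flowering_wmd_by_season
        from matchdem.io_formats import aggregate_flowers

        wmds = flowering_wmd_by_season(aggregate_flowers(flowers), true_resource_sets(cfg)["bee"])
        for _, nest in nests.iterrows():
            wmd = wmds[nest["season_year"]].wmd
            assert abs(nest["end_day"] - wmd) <= 0.5  # integer rounding only

    def test_null_effect_recovers_flat_slope(self):
        """With mismatch_effect = 0 the fitted slope is within 2 SE of zero
        in nearly all replicates."""
        from matchdem.io_formats import aggregate_flowers
        from matchdem.models import EXPONENTIAL, fit_mismatch_model
        from matchdem.phenology import flowering_wmd_by_season, nest_mismatch_table

        good = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = _tiny_config(effect=0.0, nests=40)
            rng = np.random.default_rng(seed)
            flowers = generate_flowering(cfg, rng)
            nests = generate_nests(cfg, flowers, rng)
            wmds = flowering_wmd_by_season(
                aggregate_flowers(flowers), true_resource_sets(cfg)["bee"]
            )
            data = nest_mismatch_table(nests, wmds, "bee")
            fit = fit_mismatch_model(data, "bee", EXPONENTIAL)
            good += abs(fit.slope) < 2 * fit.slope_se
        assert good >= 0.9 * n_rep

    def test_length_measured_species_carry_cavity_lengths(self, small_dataset):
        _, nests, _ = small_dataset
        measured = {"bee_B2", "bee_B3"}
        for taxon, grp in nests.groupby("bee_taxon"):
            if taxon in measured:
                assert grp["cavity_length"].notna().all()
                assert grp["brood_cells"].isna().any()
            else:
                assert grp["brood_cells"].notna().all()


class TestPollen:
    def test_point_mass_composition_gives_single_taxon_pollen(self):
        cfg = _tiny_config()
        cfg.pollen_pref_floor = 0.0
        cfg.bee_species[0].dirichlet_conc = 50.0
        flowers, nests, pollen = generate_dataset(cfg, seed=5)
        assert set(pollen["plant_taxon"]) == {"A"}
        scores = generalization_scores(pollen, nests)
        assert scores["bee"].shannon_h == 0.0

    def test_uniform_composition_approaches_ln_k(self):
        plants = [PlantSpecies(f"P{i}", 80.0, 12.0, 200.0) for i in range(4)]
        bees = [
            BeeSpecies(
                "bee",
                {f"P{i}": 0.25 for i in range(4)},
                dirichlet_conc=5000.0,
                mismatch_effect=0.0,
                mean_cells=8.0,
                nests_per_year=40,
            )
        ]
        cfg = ScenarioConfig(
            bee_species=bees, plant_species=plants, n_years=3, pollen_grains=3000.0
        )
        _, nests, pollen = generate_dataset(cfg, seed=6)
        scores = generalization_scores(pollen, nests)
        assert scores["bee"].shannon_h == pytest.approx(math.log(4), rel=0.05)


class TestDeterminismAndConfig:
    def test_generation_is_bit_reproducible(self):
        cfg = default_scenario(seed=17)
        a = generate_dataset(cfg, seed=17)
        b = generate_dataset(default_scenario(seed=17), seed=17)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_scenario(seed=3)
        scenario_to_yaml(cfg, tmp_path / "s.yaml")
        cfg2 = scenario_from_yaml(tmp_path / "s.yaml")
        a = generate_dataset(cfg, seed=3)
        b = generate_dataset(cfg2, seed=3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_invalid_configs_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError):
            _tiny_config(survey_interval=0)
        (tmp_path / "bad.yaml").write_text("just: nonsense\n")
        with pytest.raises(ConfigurationError):
            scenario_from_yaml(tmp_path / "bad.yaml")


def test_growth_generator_hits_programmed_log_growth():
    nests = generate_growth_nests(log_growth=0.2, nests_per_year=400, seed=8)
    from matchdem.demography import mean_log_growth, yearly_brood_totals

    _, lam = mean_log_growth(yearly_brood_totals(nests))
    assert lam == pytest.approx(0.2, abs=0.03)
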
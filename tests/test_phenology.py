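import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matchdem.errors import ContractError, UndefinedPhenologyError
from matchdem.phenology import (
    PhenologyEstimate,
    identify_main_resources,
    nest_mismatch,
    nesting_wmd,
    pooled_flowering_wmd,
    population_mismatch,
    weighted_mean_date,
)


class TestWeightedMeanDate:
    def test_worked_example(self):
        assert weighted_mean_date([(60, 10), (67, 60), (74, 30)]) == pytest.approx(
            68.4, abs=1e-12
        )

    @pytest.mark.parametrize(
        "obs,expected",
        [([(100, 5)], 100.0), ([(10, 3), (20, 3)], 15.0)],
    )
    def test_single_and_symmetric(self, obs, expected):
        assert weighted_mean_date(obs) == pytest.approx(expected)

    def test_undefined_without_positive_abundance(self):
        with pytest.raises(UndefinedPhenologyError):
            weighted_mean_date([])
        with pytest.raises(UndefinedPhenologyError):
            weighted_mean_date([(10, 0.0), (20, 0.0)])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 365),
                st.floats(0, 1e6, exclude_min=False),
            ),
            min_size=1,
            max_size=30,
        ),
        st.floats(1e-3, 1e3),
    )
    def test_scale_invariance_and_bounds(self, obs, c):
        """WMD uses relative weights and stays within the observed days."""
        if sum(a for _, a in obs) <= 0:
            return
        wmd = weighted_mean_date(obs)
        days = [d for d, _ in obs]
        assert min(days) - 1e-9 <= wmd <= max(days) + 1e-9
        scaled = [(d, a * c) for d, a in obs]
        assert weighted_mean_date(scaled) == pytest.approx(wmd, rel=1e-9, abs=1e-9)


class TestMainResources:
    def test_greedy_cumulative_example(self):
        res = identify_main_resources({"A": 0.50, "B": 0.30, "C": 0.15, "D": 0.05})
        assert res.plant_taxa == ("A", "B", "C")
        assert res.cumulative_share == pytest.approx(0.95)

    def test_single_resource(self):
        res = identify_main_resources({"A": 1.0})
        assert res.plant_taxa == ("A",)
        assert res.cumulative_share == pytest.approx(1.0)

    def test_equal_abundance_tie_broken_lexicographically(self):
        res = identify_main_resources({"B": 0.5, "A": 0.5})
        assert res.plant_taxa == ("A", "B")
        assert res.cumulative_share == pytest.approx(1.0)

    def test_all_zero_is_an_error(self):
        with pytest.raises(UndefinedPhenologyError):
            identify_main_resources({"A": 0.0})

    @settings(max_examples=200, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(list("ABCDEFGH")),
            st.floats(1e-6, 100),
            min_size=1,
            max_size=8,
        ),
        st.floats(0.1, 10),
    )
    def test_minimality_and_scale_invariance(self, totals, c):
        """The chosen set is minimal and independent of abundance units."""
        res = identify_main_resources(totals)
        grand = sum(totals.values())
        last_share = totals[res.plant_taxa[-1]] / grand
        assert res.cumulative_share >= res.threshold
        assert res.cumulative_share - last_share < res.threshold
        scaled = identify_main_resources({t: v * c for t, v in totals.items()})
        assert scaled.plant_taxa == res.plant_taxa


def _surveys(rows):
    return pd.DataFrame(rows, columns=["season_year", "day", "plant_taxon", "flower_count"])


class TestPooledFloweringWmd:
    def test_single_taxon_equals_its_own_wmd(self):
        surveys = _surveys([(2008, 60, "A", 10), (2008, 67, "A", 60), (2008, 74, "A", 30)])
        res = identify_main_resources({"A": 1.0}, "bee")
        est = pooled_flowering_wmd(surveys, res, 2008)
        assert est.wmd == pytest.approx(68.4)

    def test_identical_phenologies_pool_invariantly(self):
        surveys = _surveys(
            [(2008, 60, "A", 10), (2008, 70, "A", 10), (2008, 60, "B", 5), (2008, 70, "B", 5)]
        )
        res = identify_main_resources({"A": 0.6, "B": 0.4}, "bee")
        assert pooled_flowering_wmd(surveys, res, 2008).wmd == pytest.approx(65.0)

    def test_equal_totals_give_midpoint(self):
        surveys = _surveys([(2008, 60, "A", 40), (2008, 80, "B", 40)])
        res = identify_main_resources({"A": 0.5, "B": 0.5}, "bee")
        assert pooled_flowering_wmd(surveys, res, 2008).wmd == pytest.approx(70.0)

    def test_no_flowers_that_season_is_undefined(self):
        surveys = _surveys([(2008, 60, "A", 10)])
        res = identify_main_resources({"B": 1.0}, "bee")
        with pytest.raises(UndefinedPhenologyError):
            pooled_flowering_wmd(surveys, res, 2008)


def _nests(rows):
    return pd.DataFrame(
        rows, columns=["nest_id", "bee_taxon", "season_year", "end_day", "brood_cells"]
    )


class TestMismatch:
    flowering = PhenologyEstimate("resources[bee]", 2008, 68.4, 100.0)

    def test_nest_mismatch_absolute_difference(self):
        rec = nest_mismatch({"nest_id": "n1", "season_year": 2008, "end_day": 70}, self.flowering)
        assert rec.mismatch_days == pytest.approx(1.6)

    def test_nest_mismatch_zero_and_symmetry(self):
        flowering = PhenologyEstimate("r", 2008, 74.0, 1.0)
        early = nest_mismatch({"nest_id": "n", "season_year": 2008, "end_day": 60}, flowering)
        late = nest_mismatch({"nest_id": "n", "season_year": 2008, "end_day": 88}, flowering)
        assert early.mismatch_days == pytest.approx(14.0)
        assert early.mismatch_days == pytest.approx(late.mismatch_days)
        exact = nest_mismatch(
            {"nest_id": "n", "season_year": 2008, "end_day": 74}, flowering
        )
        assert exact.mismatch_days == 0.0

    def test_season_disagreement_is_a_contract_error(self):
        with pytest.raises(ContractError):
            nest_mismatch({"nest_id": "n1", "season_year": 2009, "end_day": 70}, self.flowering)

    def test_population_mismatch_mean_of_end_days(self):
        nests = _nests([("n1", "bee", 2008, 66, 4), ("n2", "bee", 2008, 70, 5)])
        rec = population_mismatch(nests, "bee", self.flowering)
        assert rec.mismatch_days == pytest.approx(0.4)

    def test_population_mismatch_single_nest_reduces_to_nest_mismatch(self):
        nests = _nests([("n1", "bee", 2008, 70, 4)])
        rec = population_mismatch(nests, "bee", self.flowering)
        assert rec.mismatch_days == pytest.approx(1.6)

    def test_population_mismatch_symmetric_nests_cancel(self):
        flowering = PhenologyEstimate("r", 2008, 70.0, 1.0)
        nests = _nests([("n1", "bee", 2008, 60, 4), ("n2", "bee", 2008, 80, 5)])
        assert population_mismatch(nests, "bee", flowering).mismatch_days == pytest.approx(0.0)

    def test_zero_nest_season_is_excluded_not_crashed(self, caplog):
        nests = _nests([])
        with caplog.at_level("WARNING", logger="matchdem.phenology"):
            rec = population_mismatch(nests, "bee", self.flowering)
        assert rec is None
        assert any("excluded" in r.message for r in caplog.records)


def test_nesting_wmd_weights_each_nest_equally():
    nests = _nests([("n1", "bee", 2008, 60, 4), ("n2", "bee", 2008, 70, 9)])
    assert nesting_wmd(nests, "bee", 2008).wmd == pytest.approx(65.0)
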
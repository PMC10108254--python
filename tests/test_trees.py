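"""Allometric biomass, increments, litterfall, and tree NPP accounting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from borealcarbon import ConfigError
from borealcarbon import trees as treelib

# stem-only coefficient set: branches/foliage/coarse roots are numerically
# negligible (exp(-60)), so the aboveground mass is the stem equation alone
STEM_ONLY = {
    "pine": {
        "stem": {"a": -2.0, "b": 10.0, "c": 12.0},
        "branches": {"a": -60.0, "b": 0.0, "c": 1.0},
        "foliage": {"a": -60.0, "b": 0.0, "c": 1.0},
        "coarse_roots": {"a": -60.0, "b": 0.0, "c": 1.0},
    },
}


class TestTreeBiomass:
    def test_zero_coefficients_give_unit_mass(self):
        coeffs = {"pine": {"stem": {"a": 0.0, "b": 0.0, "c": 5.0}}}
        assert treelib.tree_biomass(17.0, "pine", "stem", coeffs) == 1.0

    def test_hand_evaluated_value(self):
        # a=-2, b=10, c=12, dbh=12 -> exp(-2 + 10*12/24) = exp(3)
        got = treelib.tree_biomass(12.0, "pine", "stem", STEM_ONLY)
        assert got == pytest.approx(math.exp(3.0), rel=1e-12)

    def test_dbh_zero_limit(self):
        got = treelib.tree_biomass(0.0, "pine", "stem", STEM_ONLY)
        assert got == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_missing_coefficients_is_config_error(self):
        with pytest.raises(ConfigError, match="spruce"):
            treelib.tree_biomass(10.0, "spruce", "stem", STEM_ONLY)

    @given(st.floats(min_value=0.1, max_value=80.0),
           st.floats(min_value=0.2, max_value=80.0))
    def test_strictly_increasing_in_dbh(self, d1, delta):
        b1 = treelib.tree_biomass(d1, "pine", "stem", STEM_ONLY)
        b2 = treelib.tree_biomass(d1 + delta, "pine", "stem", STEM_ONLY)
        assert b2 > b1


class TestStandPools:
    def _tree(self, dbh, status="live", decay=np.nan, tid="T1"):
        return {"stand_id": "A", "tree_id": tid, "year": 2016, "dbh": dbh,
                "species": "pine", "status": status, "decay_class": decay}

    def test_no_trees_gives_zero_pools(self):
        pools = treelib.stand_biomass_pools(
            pd.DataFrame(columns=["stand_id", "tree_id", "year", "dbh",
                                  "species", "status", "decay_class"]),
            10.0, STEM_ONLY, {1: 0.9})
        assert all(v == 0.0 for v in pools.values())

    def test_hand_scaled_aboveground_pool(self):
        # two live trees of exp(3) = 20.0855 kg each on a 10 m radius plot:
        # 40.171 kg / 314.159 m2 = 0.12787 kg m-2 = 1.2787 Mg ha-1
        trees = pd.DataFrame([self._tree(12.0, tid="T1"),
                              self._tree(12.0, tid="T2")])
        pools = treelib.stand_biomass_pools(trees, 10.0, STEM_ONLY, {1: 0.9})
        assert pools["live_above_mg_ha"] == pytest.approx(1.2787, abs=2e-4)

    def test_pools_linear_in_tree_count(self):
        one = pd.DataFrame([self._tree(15.0)])
        two = pd.DataFrame([self._tree(15.0, tid="T1"),
                            self._tree(15.0, tid="T2")])
        p1 = treelib.stand_biomass_pools(one, 10.0, STEM_ONLY, {1: 0.9})
        p2 = treelib.stand_biomass_pools(two, 10.0, STEM_ONLY, {1: 0.9})
        assert p2["live_above_gc_m2"] == pytest.approx(
            2 * p1["live_above_gc_m2"], rel=1e-12)

    def test_dead_tree_density_ratio_is_proportional(self):
        live = pd.DataFrame([self._tree(12.0)])
        dead = pd.DataFrame([self._tree(12.0, status="dead_standing",
                                        decay=3.0)])
        p_live = treelib.stand_biomass_pools(live, 10.0, STEM_ONLY, {3: 0.5})
        p_dead = treelib.stand_biomass_pools(dead, 10.0, STEM_ONLY, {3: 0.5})
        assert p_dead["dead_above_mg_ha"] == pytest.approx(
            0.5 * p_live["live_above_mg_ha"], rel=1e-12)

    def test_unknown_decay_class_is_error(self):
        dead = pd.DataFrame([self._tree(12.0, status="dead_standing",
                                        decay=4.0)])
        with pytest.raises(Exception, match="decay class 4"):
            treelib.stand_biomass_pools(dead, 10.0, STEM_ONLY, {1: 0.9})


class TestAnnualIncrement:
    def test_linear_interpolation_across_two_years(self):
        inc = treelib.annual_increment({2016: 10.0, 2018: 10.6})
        assert inc[2017] == pytest.approx(0.3)
        assert inc[2018] == pytest.approx(0.3)

    def test_constant_dbh_gives_zero(self):
        inc = treelib.annual_increment({2016: 10.0, 2017: 10.0})
        assert inc[2017] == 0.0

    def test_ring_width_backcasting_doubles_radial_growth(self):
        # ring width 1.5 mm -> DBH increment 0.3 cm yr-1
        inc = treelib.annual_increment({2018: 12.0},
                                       ring_widths_mm=[1.5, 1.5])
        assert inc[2018] == pytest.approx(0.3)
        assert inc[2017] == pytest.approx(0.3)

    def test_shrinking_dbh_clamped_to_zero(self):
        inc = treelib.annual_increment({2016: 10.0, 2017: 9.5})
        assert inc[2017] == 0.0


class TestProductionArithmetic:
    @pytest.mark.parametrize("args,expected", [
        ((0.0, 0.0, 0.0), 0.0),
        ((100.0, 0.0, 50.0), 150.0),
        ((80.0, 20.0, 40.0), 140.0),
    ])
    def test_anpp_trees(self, args, expected):
        assert treelib.anpp_trees(*args) == expected

    @pytest.mark.parametrize("args,expected", [
        ((0.0, 0.0), 0.0), ((30.0, 5.0), 35.0), ((-10.0, 5.0), -5.0),
    ])
    def test_bnpp_coarse_roots_passes_sign_through(self, args, expected):
        assert treelib.bnpp_coarse_roots(*args) == expected

    @pytest.mark.parametrize("masses,area,cfrac,expected", [
        ([0.0, 0.0, 0.0], 0.25, 0.5, 0.0),
        ([50.0, 50.0, 50.0], 0.25, 0.5, 100.0),
        ([0.25, 0.25, 0.25], 0.25, 1.0, 1.0),
    ])
    def test_litterfall_annual(self, masses, area, cfrac, expected):
        got = treelib.litterfall_annual(masses, area, cfrac)
        assert got == pytest.approx(expected, rel=1e-12)


class TestClearcutImputation:
    def test_linear_interpolation_between_references(self):
        biomass, litter = treelib.impute_clearcut_tree_components(
            15.0, [10.0, 20.0], [20.0, 40.0], [5.0, 15.0])
        assert biomass == pytest.approx(30.0)
        assert litter == pytest.approx(10.0)

    def test_reference_age_returns_reference_value(self):
        biomass, _ = treelib.impute_clearcut_tree_components(
            20.0, [10.0, 20.0], [20.0, 40.0], [1.0, 1.0])
        assert biomass == pytest.approx(40.0)

    def test_negative_extrapolation_clamped(self):
        biomass, _ = treelib.impute_clearcut_tree_components(
            2.0, [10.0, 20.0], [20.0, 60.0], [1.0, 1.0])
        assert biomass == 0.0      # line 4a - 20 gives -12 at age 2

    def test_single_reference_is_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            treelib.impute_clearcut_tree_components(5.0, [10.0], [20.0],
                                                    [1.0])


class TestStandProductionSeries:
    AREA = math.pi * 100.0
    TO_GC = 0.5 * 1000.0 / AREA

    def _table(self, rows):
        return pd.DataFrame(rows, columns=["stand_id", "tree_id", "year",
                                           "dbh", "species", "status",
                                           "decay_class"])

    def test_growth_of_single_tree(self):
        rows = [("A", "T1", 2016, 12.0, "pine", "live", np.nan),
                ("A", "T1", 2017, 13.0, "pine", "live", np.nan)]
        out = treelib.stand_production_series(self._table(rows),
                                              {2017: 10.0}, 10.0,
                                              STEM_ONLY, {1: 0.9})
        expected_delta = (math.exp(-2 + 10 * 13 / 25)
                          - math.exp(-2 + 10 * 12 / 24)) * self.TO_GC
        assert out.loc[2017, "delta_b_live_above"] == pytest.approx(
            expected_delta, rel=1e-9)
        assert out.loc[2017, "anpp_t"] == pytest.approx(
            expected_delta + 10.0, rel=1e-9)

    def test_mortality_contributes_growth_only(self):
        # tree grows 12 -> 13 then is found dead: net NPP = growth
        rows = [("A", "T1", 2016, 12.0, "pine", "live", np.nan),
                ("A", "T1", 2017, 13.0, "pine", "dead_standing", 1.0)]
        out = treelib.stand_production_series(self._table(rows), {}, 10.0,
                                              STEM_ONLY, {1: 0.9})
        b0 = math.exp(-2 + 10 * 12 / 24)
        b1 = math.exp(-2 + 10 * 13 / 25)
        assert out.loc[2017, "mortality_above"] == pytest.approx(
            b1 * self.TO_GC, rel=1e-9)
        assert out.loc[2017, "anpp_t"] == pytest.approx(
            (b1 - b0) * self.TO_GC, rel=1e-9)

    def test_removed_trees_do_not_count_as_loss(self):
        rows = [("A", "T1", 2016, 12.0, "pine", "live", np.nan),
                ("A", "T2", 2016, 12.0, "pine", "live", np.nan),
                ("A", "T1", 2017, 13.0, "pine", "live", np.nan),
                ("A", "T2", 2017, 12.0, "pine", "removed", np.nan)]
        out = treelib.stand_production_series(self._table(rows), {}, 10.0,
                                              STEM_ONLY, {1: 0.9})
        expected = (math.exp(-2 + 10 * 13 / 25)
                    - math.exp(-2 + 10 * 12 / 24)) * self.TO_GC
        assert out.loc[2017, "anpp_t"] == pytest.approx(expected, rel=1e-9)
        assert out.loc[2017, "anpp_t"] > 0
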
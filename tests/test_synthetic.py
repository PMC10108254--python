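"""The synthetic field campaign: design counts, determinism, and the
consistency of emitted measurements with the ground truth."""

import numpy as np
import pandas as pd
import pytest

from borealcarbon import generate_landscape, load_config
from borealcarbon.io import check_budget_identities
from borealcarbon.respiration import lloyd_taylor
from borealcarbon.synthetic import noise_free


class TestDesign:
    def test_default_design_counts(self, full_noise_free):
        _, bundle, _, _ = full_noise_free
        stands = bundle["stands"]
        assert len(stands) == 50
        counts = stands["age_class"].value_counts()
        assert counts["initiation"] == 8 and counts["young"] == 9
        assert counts["middle_aged"] == 13 and counts["mature"] == 14
        assert counts["old"] == 6
        assert (stands["species_group"] == "pine").sum() == 28
        assert (stands["species_group"] == "spruce").sum() == 22
        assert (stands["soil_type"] == "till").sum() == 35
        assert (stands["soil_type"] == "sediment").sum() == 15

    def test_age_ranges_per_class(self, full_noise_free):
        _, bundle, _, _ = full_noise_free
        stands = bundle["stands"]
        bounds = {"initiation": (5, 27), "young": (31, 58),
                  "middle_aged": (61, 78), "mature": (80, 105),
                  "old": (131, 211)}
        for cls, (lo, hi) in bounds.items():
            ages = stands.loc[stands["age_class"] == cls, "age"]
            assert ages.between(lo, hi).all()

    def test_clearcuts_have_no_inventory_trees(self, full_noise_free):
        _, bundle, _, _ = full_noise_free
        stands = bundle["stands"]
        cc = set(stands.loc[stands["age"] <= 7, "stand_id"])
        assert len(cc) == 3
        assert cc.isdisjoint(set(bundle["trees"]["stand_id"]))

    def test_zero_stand_landscape_is_empty(self):
        cfg = load_config(overrides={"synthetic": {
            "class_counts": {c: 0 for c in ("initiation", "young",
                                            "middle_aged", "mature", "old")},
            "n_clearcuts": 0, "include_thinned_stand": False,
            "include_source_clearcut": False}})
        bundle, truth = generate_landscape(cfg, seed=1)
        assert len(bundle["stands"]) == 0
        assert len(truth.budgets) == 0


class TestDeterminism:
    def test_same_seed_gives_identical_bundles(self, small_config):
        cfg = noise_free(small_config)
        b1, t1 = generate_landscape(cfg, seed=5)
        b2, t2 = generate_landscape(cfg, seed=5)
        for name in b1:
            pd.testing.assert_frame_equal(b1[name], b2[name])
        pd.testing.assert_frame_equal(t1.budgets, t2.budgets)

    def test_different_seeds_differ(self, small_config):
        cfg = noise_free(small_config)
        _, t1 = generate_landscape(cfg, seed=5)
        _, t2 = generate_landscape(cfg, seed=6)
        assert not t1.budgets["nep"].equals(t2.budgets["nep"])


class TestInventories:
    def test_live_dbh_non_decreasing(self, small_noise_free):
        _, bundle, _ = small_noise_free
        trees = bundle["trees"]
        for _, grp in trees[trees["status"] == "live"].groupby(
                ["stand_id", "tree_id"]):
            dbh = grp.sort_values("year")["dbh"].to_numpy()
            assert (np.diff(dbh) >= -1e-12).all()

    def test_dead_trees_enter_decay_class_one(self, small_noise_free):
        _, bundle, _ = small_noise_free
        dead = bundle["trees"][bundle["trees"]["status"] == "dead_standing"]
        assert (dead["decay_class"] == 1.0).all()

    def test_thinned_stand_has_removed_trees_in_final_year(
            self, full_noise_free):
        _, bundle, _, _ = full_noise_free
        removed = bundle["trees"][bundle["trees"]["status"] == "removed"]
        assert len(removed) > 0
        assert removed["year"].nunique() == 1
        assert removed["year"].iloc[0] == bundle["trees"]["year"].max()


class TestTruth:
    def test_truth_budgets_satisfy_identities_exactly(self, full_noise_free):
        _, _, truth, _ = full_noise_free
        check_budget_identities(truth.budgets, rtol=1e-12)

    def test_truth_components_non_negative(self, full_noise_free):
        _, _, truth, _ = full_noise_free
        for col in ("npp", "npp_t", "npp_u", "rh_s", "rh_dw", "rh"):
            assert (truth.budgets[col] >= 0).all()

    def test_source_clearcut_is_net_emitter(self, full_noise_free):
        _, bundle, truth, _ = full_noise_free
        stands = bundle["stands"]
        cc = sorted(stands.loc[stands["age"] <= 7, "stand_id"])[-1]
        mean_nep = truth.budgets.groupby("stand_id")["nep"].mean()
        assert mean_nep[cc] < 0


class TestChamberCampaigns:
    def test_noise_free_fluxes_equal_lloyd_taylor_model(
            self, small_noise_free):
        """Chamber slope recomputation returns the plot's true temperature
        response evaluated at the campaign soil temperature."""
        _, bundle, truth = small_noise_free
        lt = truth.lloyd_taylor.set_index("stand_id")
        ch = bundle["chambers"]
        for (sid, cid), grp in list(ch.groupby(["stand_id",
                                                "campaign_id"]))[:20]:
            ts = grp["ts_c"].iloc[0]
            expected = lloyd_taylor(ts, lt.loc[sid, "r_ref"],
                                    lt.loc[sid, "e0"])
            t = grp["seconds"].to_numpy()
            slope = np.polyfit(t[t >= 10], grp["ppm"].to_numpy()[t >= 10], 1)[0]
            molar = 101.325e3 / (8.314 * (grp["ta_bc_c"].iloc[0] + 273.15))
            assert slope * 0.20 * molar == pytest.approx(expected, rel=1e-9)

    def test_campaign_count_per_stand_year(self, small_noise_free):
        _, bundle, _ = small_noise_free
        ch = bundle["chambers"]
        per = ch.groupby(["stand_id", "campaign_id"]).size().reset_index()
        counts = per.groupby("stand_id").size()
        assert (counts == 24).all()      # 8 campaigns x 3 study years

    def test_litter_traps_scale_back_to_truth(self, small_noise_free):
        _, bundle, truth = small_noise_free
        litter = bundle["litter"]
        truth_l = truth.budgets.set_index(["stand_id", "year"])["l"]
        for (sid, year), grp in litter.groupby(["stand_id", "year"]):
            got = 0.5 * grp["dry_mass_g"].sum() / (3 * 0.25)
            assert got == pytest.approx(truth_l[(sid, year)], rel=1e-9)
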
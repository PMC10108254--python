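"""Flux-age trend fitting, class aggregation, and budget composition."""

import math

import numpy as np
import pandas as pd
import pytest

from borealcarbon import AgeTrendModel, ValidationError, fit_poly2, nep_trend
from borealcarbon.budgets import (OldStandReference, class_aggregate,
                                  compose_budget, impute_old_stand_budget)
from borealcarbon.domain import BUDGET_COMPONENTS


def _log_space_oracle(ages, values):
    """Closed-form 3x3 solve of ln(y) on [1, ln a, ln^2 a]."""
    x = np.log(np.asarray(ages, dtype=float))
    design = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(design, np.log(values), rcond=None)
    return coef


class TestLogQuadratic:
    def test_exact_data_recovers_coefficients(self):
        b = (1.0, 0.5, -0.05)
        ages = np.array([1.0, math.e, math.e ** 2, math.e])
        x = np.log(ages)
        values = np.exp(b[0] + b[1] * x + b[2] * x * x)
        oracle = _log_space_oracle(ages, values)
        fit = AgeTrendModel(ages, values, form="log_quadratic").fit()
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-6)
        np.testing.assert_allclose(fit.coefficients, b, atol=1e-6)

    def test_constant_data_gives_log_constant(self):
        fit = AgeTrendModel([5, 20, 80, 150], [7.0, 7.0, 7.0, 7.0],
                            form="log_quadratic").fit()
        assert fit.b0 == pytest.approx(math.log(7.0), abs=1e-8)
        assert fit.b1 == pytest.approx(0.0, abs=1e-8)
        assert fit.b2 == pytest.approx(0.0, abs=1e-8)

    def test_hump_peak_age_identity(self):
        b = (0.5, 2.4, -0.3)
        ages = np.array([5.0, 20.0, 60.0, 150.0, 210.0])
        x = np.log(ages)
        values = np.exp(b[0] + b[1] * x + b[2] * x * x)
        fit = AgeTrendModel(ages, values, form="log_quadratic").fit()
        peak = fit.peak_age()
        assert peak == pytest.approx(math.exp(-b[1] / (2 * b[2])), rel=1e-6)
        grid = np.linspace(1, 220, 4000)
        assert abs(grid[np.argmax(fit.predict(grid))]
                   - peak) < 0.2
    def test_natural_scale_fit_no_worse_than_log_space_on_noisy_data(self):
        rng = np.random.default_rng(5)
        ages = np.linspace(5, 210, 50)
        x = np.log(ages)
        clean = np.exp(0.3 + 2.5 * x - 0.29 * x * x)
        noisy = clean * (1 + 0.25 * rng.standard_normal(ages.size))
        noisy = np.maximum(noisy, 1.0)
        fit = AgeTrendModel(ages, noisy, form="log_quadratic").fit()
        beta = _log_space_oracle(ages, noisy)
        pred_log = np.exp(beta[0] + beta[1] * x + beta[2] * x * x)
        rmse_log = np.sqrt(np.mean((noisy - pred_log) ** 2))
        assert fit.rmse <= rmse_log + 1e-9

    def test_age_below_one_rejected(self):
        with pytest.raises(ValueError, match="ages >= 1"):
            AgeTrendModel([0.5, 5, 10, 20], [1, 2, 3, 4],
                          form="log_quadratic")


class TestPoly2:
    def test_constant_data(self):
        fit = fit_poly2([10, 50, 90], [4.0, 4.0, 4.0])
        assert fit.coefficients == pytest.approx((4.0, 0.0, 0.0), abs=1e-9)

    def test_exact_parabola_hand_solved(self):
        fit = fit_poly2([10, 50, 90], [5.0, 9.0, 5.0])
        assert fit.b0 == pytest.approx(2.75, abs=1e-9)
        assert fit.b1 == pytest.approx(0.25, abs=1e-9)
        assert fit.b2 == pytest.approx(-0.0025, abs=1e-9)

    def test_symmetric_data_vertex_at_mean_age(self):
        ages = [20, 40, 60, 80]
        vals = [1.0, 3.0, 3.0, 1.0]
        fit = fit_poly2(ages, vals)
        assert -fit.b1 / (2 * fit.b2) == pytest.approx(50.0, rel=1e-9)

    def test_negative_predictions_clamped(self):
        fit = fit_poly2([10, 50, 90], [5.0, 9.0, 5.0])
        assert fit.predict(400.0) == 0.0


class TestNepTrend:
    def test_equal_fits_give_zero(self):
        f = fit_poly2([10, 50, 90], [5.0, 9.0, 5.0])
        curve = nep_trend(f, f)
        assert curve(37.0) == 0.0

    def test_constant_difference(self):
        npp = fit_poly2([10, 50, 90], [391.0] * 3)
        rh = fit_poly2([10, 50, 90], [217.0] * 3)
        assert nep_trend(npp, rh)(123.0) == pytest.approx(174.0, abs=1e-9)

    def test_matches_truth_curve_on_noise_free_landscape(self,
                                                         full_noise_free):
        _, _, truth, results = full_noise_free
        p = truth.curves["npp_t"]
        for age in (30.0, 60.0, 90.0):
            truth_npp_t = math.exp(p["b0"] + p["b1"] * math.log(age)
                                   + p["b2"] * math.log(age) ** 2)
            got = results.trend_fits["npp_t"].predict(age)
            assert got == pytest.approx(truth_npp_t, rel=0.10)


def _budget_df(values):
    rows = []
    for sid, year, nep_parts in values:
        rows.append(compose_budget(sid, year, nep_parts).__dict__)
    return pd.DataFrame(rows)[["stand_id", "year", *BUDGET_COMPONENTS]]


BASE = {"anpp_t": 150.0, "l": 40.0, "bnpp_t_cr": 30.0, "bnpp_t_fr": 60.0,
        "anpp_u": 40.0, "bnpp_u": 20.0, "rh_s": 210.0, "rh_dw": 8.0}


class TestComposeBudget:
    def test_all_zero_components_give_zero_nep(self):
        b = compose_budget("A", 2016, {k: 0.0 for k in BASE})
        assert b.nep == 0.0

    def test_hand_summed_example(self):
        b = compose_budget("A", 2016, BASE)
        assert b.npp_t == 240.0 and b.npp_u == 60.0
        assert b.npp == 300.0 and b.rh == 218.0
        assert b.nep == pytest.approx(82.0)
        b.check_identities()

    def test_missing_component_named(self):
        parts = {k: v for k, v in BASE.items() if k != "rh_s"}
        with pytest.raises(ValidationError, match="rh_s"):
            compose_budget("A", 2016, parts)

    def test_negative_component_rejected_unless_clamped(self):
        parts = dict(BASE, anpp_u=-5.0)
        with pytest.raises(ValidationError, match="anpp_u"):
            compose_budget("A", 2016, parts)
        b = compose_budget("A", 2016, parts, clamp_negative=True)
        assert b.anpp_u == 0.0
        b.check_identities()


class TestClassAggregate:
    def _stands(self, ids, cls="young"):
        return pd.DataFrame({"stand_id": ids, "age": 40,
                             "age_class": cls, "species_group": "pine",
                             "soil_type": "till", "plot_radius": 10.0,
                             "additional": 0})

    def test_t_interval_hand_computed(self):
        rows = []
        for sid, v in zip("ABC", (1.0, 2.0, 3.0)):
            rows.append((sid, 2016, dict(BASE, rh_s=BASE["rh_s"] - v)))
        budgets = _budget_df(rows)
        out = class_aggregate(budgets, self._stands(list("ABC")))
        nep = out[out["flux"] == "nep"].iloc[0]
        assert nep["mean"] == pytest.approx(84.0)       # 82 + mean{1,2,3}
        assert nep["ci95_half_width"] == pytest.approx(2.484, abs=1e-3)

    def test_single_stand_ci_undefined(self):
        budgets = _budget_df([("A", 2016, BASE)])
        out = class_aggregate(budgets, self._stands(["A"]))
        assert np.isnan(out[out["flux"] == "nep"]["ci95_half_width"]).all()

    def test_identical_values_zero_ci(self):
        budgets = _budget_df([(s, 2016, BASE) for s in "ABC"])
        out = class_aggregate(budgets, self._stands(list("ABC")))
        assert out[out["flux"] == "nep"]["ci95_half_width"].iloc[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_multi_year_means_taken_before_classing(self):
        rows = [("A", 2016, dict(BASE, rh_s=200.0)),
                ("A", 2017, dict(BASE, rh_s=220.0)),
                ("B", 2016, dict(BASE, rh_s=210.0))]
        out = class_aggregate(_budget_df(rows), self._stands(list("AB")))
        rh_s = out[out["flux"] == "rh_s"].iloc[0]
        assert rh_s["n"] == 2
        assert rh_s["mean"] == pytest.approx(210.0)


class TestOldStandImputation:
    def _reference(self):
        # five stands whose RH_s is exactly linear in BA: 200 + 2*(BA-20)
        rows = []
        bas = [20.0, 25.0, 30.0, 35.0, 40.0]
        for i, ba in enumerate(bas):
            parts = dict(BASE, rh_s=200.0 + 2.0 * (ba - 20.0))
            rows.append((f"S{i}", 2016, parts))
        budgets = _budget_df(rows)
        ba = pd.Series(bas, index=[f"S{i}" for i in range(5)])
        return OldStandReference(budgets, ba)

    def test_rh_s_regression_interpolates(self):
        ref = self._reference()
        b = impute_old_stand_budget("X", 2016, 30.0, 110.0, 30.0, ref)
        assert b.rh_s == pytest.approx(220.0, rel=1e-9)

    def test_degenerate_reference_reproduces_proportions(self):
        ref = self._reference()
        # measured growth part equals the reference growth (150-40=110)
        b = impute_old_stand_budget("X", 2016, 30.0, 110.0, 30.0, ref)
        assert b.l == pytest.approx(BASE["l"], rel=1e-9)
        assert b.anpp_t == pytest.approx(BASE["anpp_t"], rel=1e-9)
        assert b.bnpp_t_fr == pytest.approx(BASE["bnpp_t_fr"], rel=1e-9)
        assert b.anpp_u == pytest.approx(BASE["anpp_u"], rel=1e-9)
        b.check_identities()

    def test_too_few_reference_stands(self):
        budgets = _budget_df([("A", 2016, BASE), ("B", 2016, BASE)])
        with pytest.raises(ValueError, match=">= 5"):
            OldStandReference(budgets, pd.Series([20.0, 30.0],
                                                 index=["A", "B"]))
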
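"""Chamber fluxes, Lloyd-Taylor fitting, and annual respiration sums."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from borealcarbon import ChamberMeasurement, ConfigError, ValidationError
from borealcarbon import respiration as resp


def _measurement(slope_ppm_s, ta_c=20.0, height=0.20, n=13, dt=15.0):
    t = np.arange(n) * dt
    return ChamberMeasurement(
        stand_id="A", timestamp="2017-07-01 12:00", seconds=t.tolist(),
        ppm=(420.0 + slope_ppm_s * t).tolist(), ts_c=10.0, swc_pct=30.0,
        ta_bc_c=ta_c, pressure_kpa=101.325, height_m=height)


class TestChamberFlux:
    def test_constant_concentration_gives_zero(self):
        assert resp.chamber_flux(_measurement(0.0)) == 0.0

    def test_ideal_gas_worked_example(self):
        # slope 1 ppm/s, V/A = 0.2 m, 101.325 kPa, 20 degC -> 8.314
        got = resp.chamber_flux(_measurement(1.0))
        assert got == pytest.approx(8.314, abs=2e-3)

    def test_flux_proportional_to_chamber_height(self):
        f1 = resp.chamber_flux(_measurement(1.0, height=0.20))
        f2 = resp.chamber_flux(_measurement(1.0, height=0.40))
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_too_few_points_after_deadband_is_error(self):
        m = _measurement(1.0, n=6, dt=2.0)    # only one point beyond 10 s
        with pytest.raises(ValidationError, match="deadband"):
            resp.chamber_flux(m)

    def test_negative_slope_clamped_to_zero(self):
        assert resp.chamber_flux(_measurement(-0.5)) == 0.0


class TestLloydTaylorFunction:
    def test_reference_temperature_identity(self):
        assert resp.lloyd_taylor(10.0, 2.5, 308.56) == pytest.approx(2.5)

    def test_hand_evaluation_at_20c(self):
        got = resp.lloyd_taylor(20.0, 2.0, 308.56)
        assert got == pytest.approx(4.607, abs=1e-3)


def _grid_oracle(ts_c, flux, e0_grid):
    """Brute-force: closed-form R_ref at each E0 node, pick the SSE min."""
    best = (np.inf, None, None)
    for e0 in e0_grid:
        g = resp.lloyd_taylor(np.asarray(ts_c), 1.0, e0)
        r_ref = float(g @ np.asarray(flux)) / float(g @ g)
        sse = float(np.sum((np.asarray(flux) - r_ref * g) ** 2))
        if sse < best[0]:
            best = (sse, r_ref, e0)
    return best


class TestLloydTaylorFit:
    TEMPS = np.array([5.0, 10.0, 15.0, 20.0])

    def test_temperature_insensitive_data_gives_constant_model(self):
        flux = np.full(4, 3.0)
        fit = resp.fit_lloyd_taylor(self.TEMPS, flux)
        assert fit.r_ref == pytest.approx(3.0, rel=1e-6)
        assert fit.e0 == pytest.approx(0.0, abs=1e-3)

    def test_noise_free_parameter_recovery(self):
        flux = resp.lloyd_taylor(self.TEMPS, 2.0, 308.56)
        fit = resp.fit_lloyd_taylor(self.TEMPS, flux)
        assert fit.r_ref == pytest.approx(2.0, rel=1e-4)
        assert fit.e0 == pytest.approx(308.56, rel=1e-4)

    def test_prediction_at_reference_returns_r_ref(self):
        flux = resp.lloyd_taylor(self.TEMPS, 2.0, 308.56)
        fit = resp.fit_lloyd_taylor(self.TEMPS, flux)
        assert fit.predict(10.0) == pytest.approx(fit.r_ref, rel=1e-12)

    def test_fit_beats_grid_oracle(self):
        rng = np.random.default_rng(42)
        temps = np.linspace(3.0, 16.0, 8)
        for _ in range(5):
            r_ref = rng.uniform(0.5, 4.0)
            e0 = rng.uniform(100.0, 450.0)
            flux = resp.lloyd_taylor(temps, r_ref, e0)
            fit = resp.fit_lloyd_taylor(temps, flux)
            sse_fit = float(np.sum((fit.predict(temps) - flux) ** 2))
            sse_grid, _, _ = _grid_oracle(temps, flux,
                                          np.arange(0.0, 600.0, 10.0))
            assert sse_fit <= sse_grid + 1e-12

    def test_narrow_temperature_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            resp.LloydTaylorModel([10.0, 11.0, 12.0, 13.0],
                                  [1.0, 1.1, 1.2, 1.3])

    def test_summary_mentions_parameters(self):
        flux = resp.lloyd_taylor(self.TEMPS, 2.0, 308.56)
        text = resp.fit_lloyd_taylor(self.TEMPS, flux).summary()
        assert "R_ref" in text and "E0" in text


HALFHOURS_PER_YEAR = 17520


class TestAnnualRhs:
    def test_zero_r_ref_gives_zero(self):
        model = resp.LloydTaylorResults(0.0, 300.0, 0.0, 8)
        ts = np.full(HALFHOURS_PER_YEAR, 10.0)
        assert resp.annual_rhs(model, ts) == 0.0

    def test_constant_10c_hand_sum(self):
        # 1 umol m-2 s-1 for 31,536,000 s -> 378.78 g C m-2 yr-1
        model = resp.LloydTaylorResults(1.0, 308.56, 0.0, 8)
        ts = np.full(HALFHOURS_PER_YEAR, 10.0)
        assert resp.annual_rhs(model, ts) == pytest.approx(378.78, abs=0.01)

    def test_constant_20c_hand_sum(self):
        model = resp.LloydTaylorResults(1.0, 308.56, 0.0, 8)
        ts = np.full(HALFHOURS_PER_YEAR, 20.0)
        assert resp.annual_rhs(model, ts) == pytest.approx(872.5, abs=0.5)

    def test_monotone_in_r_ref_and_temperature(self):
        ts = 5.0 + 8.0 * np.sin(np.linspace(0, 2 * np.pi,
                                            HALFHOURS_PER_YEAR))
        low = resp.LloydTaylorResults(1.0, 308.56, 0.0, 8)
        high = resp.LloydTaylorResults(1.5, 308.56, 0.0, 8)
        assert resp.annual_rhs(high, ts) > resp.annual_rhs(low, ts)
        assert resp.annual_rhs(low, ts + 1.0) > resp.annual_rhs(low, ts)

    def test_gap_interpolation_and_threshold(self):
        model = resp.LloydTaylorResults(1.0, 308.56, 0.0, 8)
        ts = np.full(HALFHOURS_PER_YEAR, 10.0)
        ts_gappy = ts.copy()
        ts_gappy[100:200] = np.nan                      # ~0.6% gap
        assert resp.annual_rhs(model, ts_gappy) == pytest.approx(
            resp.annual_rhs(model, ts), rel=1e-9)
        ts_bad = ts.copy()
        ts_bad[:2000] = np.nan                          # >5% gap
        with pytest.raises(ValueError, match="gap"):
            resp.annual_rhs(model, ts_bad)


K_TABLE = {"pine": {"standing": {2: 0.04}, "downed": {3: 0.0}}}


def _pools(rows):
    return pd.DataFrame(rows, columns=["stand_id", "year", "position",
                                       "species", "decay_class",
                                       "carbon_mass_g_m2"])


class TestAnnualRhdw:
    def test_empty_pools_give_zero(self):
        assert resp.annual_rhdw(_pools([]), K_TABLE) == 0.0

    def test_exponential_year_step(self):
        pools = _pools([("A", 2016, "standing", "pine", 2, 500.0)])
        got = resp.annual_rhdw(pools, K_TABLE)
        assert got == pytest.approx(500.0 * (1 - np.exp(-0.04)), rel=1e-12)
        assert got == pytest.approx(19.61, abs=0.01)

    def test_zero_rate_constant_gives_zero(self):
        pools = _pools([("A", 2016, "downed", "pine", 3, 500.0)])
        assert resp.annual_rhdw(pools, K_TABLE) == 0.0

    def test_linear_mode(self):
        pools = _pools([("A", 2016, "standing", "pine", 2, 500.0)])
        assert resp.annual_rhdw(pools, K_TABLE,
                                mode="linear") == pytest.approx(20.0)

    def test_missing_rate_constant_names_the_key(self):
        pools = _pools([("A", 2016, "standing", "spruce", 2, 10.0)])
        with pytest.raises(ConfigError, match="spruce"):
            resp.annual_rhdw(pools, K_TABLE)


class TestTotalRh:
    @pytest.mark.parametrize("rh_s,rh_dw,expected",
                             [(0.0, 0.0, 0.0), (210.0, 8.0, 218.0)])
    def test_exact_sum(self, rh_s, rh_dw, expected):
        assert resp.total_rh(rh_s, rh_dw) == expected

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            resp.total_rh(-1.0, 0.0)

    def test_deadwood_share_below_5pct_on_default_landscape(
            self, full_noise_free):
        _, _, truth, _ = full_noise_free
        share = truth.budgets["rh_dw"] / truth.budgets["rh"]
        assert (share < 0.05).all()
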
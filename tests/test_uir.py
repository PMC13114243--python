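"""Unit impulse response, closed-form convolution, and deconvolution."""

import numpy as np
import pytest
from scipy.integrate import quad
from sklearn.base import clone

from sparsepk import (
    UIR,
    MacroModel,
    StaircaseDeconvolver,
    convolve_staircase,
    deconvolve,
    simulate_first_order_sq,
    uir_auc,
    uir_eval,
    uir_from_fit,
)
from tests.conftest import CAB_TRUTH, MPA_TRUTH

CAB_UIR = UIR(((0.252, 4.52), (0.458, 0.053)), dose_ug=60.0, analyte="CAB")


class TestNormalization:
    def test_cab_coefficients_match_printed_uir(self):
        model = MacroModel(
            ((CAB_TRUTH["A"], 4.52), (CAB_TRUTH["B"], 0.053))
        )
        uir = uir_from_fit(model, dose_ug=66.0)
        assert round(uir.terms[0][0], 3) == 0.252
        assert round(uir.terms[1][0], 3) == 0.458

    def test_mpa_coefficients_match_printed_uir(self):
        model = MacroModel(((MPA_TRUTH["A"], 10.5), (MPA_TRUTH["B"], 0.65)))
        uir = uir_from_fit(model, dose_ug=65.0)
        assert round(uir.terms[0][0], 4) == 0.0386
        assert round(uir.terms[1][0], 5) == 0.00675

    def test_unit_arithmetic(self):
        uir = uir_from_fit(MacroModel(((1e6, 1.0),)), dose_ug=1000.0)
        assert uir.terms[0][0] == pytest.approx(1.0)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError, match="dose"):
            uir_from_fit(MacroModel(((1.0, 1.0),)), dose_ug=0.0)


class TestEval:
    def test_t0_is_sum_of_coefficients(self):
        assert uir_eval(CAB_UIR, 0.0) == pytest.approx(0.710)

    def test_vanishes_at_late_time_and_halves_per_half_life(self):
        assert uir_eval(CAB_UIR, 500.0) < 1e-7
        mono = UIR(((1.0, 0.2),))
        th = np.log(2) / 0.2
        assert uir_eval(mono, th) == pytest.approx(0.5)
        with pytest.raises(ValueError, match="non-negative"):
            uir_eval(mono, -1.0)

    def test_invalid_uir_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            UIR(((1.0, 0.5), (1.0, 0.5)))
        with pytest.raises(ValueError, match="> 0"):
            UIR(((-1.0, 0.5),))


class TestConvolution:
    def test_zero_rates_give_zero_concentration(self):
        c = convolve_staircase(CAB_UIR, [0, 1, 2], [0.0, 0.0], [0.5, 1.5, 3.0])
        np.testing.assert_array_equal(c, 0.0)

    def test_instantaneous_bolus_limit(self):
        eps = 1e-6
        dose_ng = 1000.0
        t = np.array([0.5, 2.0, 10.0])
        c = convolve_staircase(CAB_UIR, [0, eps], [dose_ng / eps], t)
        np.testing.assert_allclose(c, dose_ng * uir_eval(CAB_UIR, t), rtol=1e-5)

    def test_matches_adaptive_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        knots = np.array([0.0, 0.5, 1.5, 3.0, 6.0])
        rates = rng.uniform(0.0, 2000.0, size=4)

        def oracle(t):
            total = 0.0
            for a, b, r in zip(knots[:-1], knots[1:], rates):
                if t <= a or r == 0:
                    continue
                hi = min(t, b)
                val, _ = quad(
                    lambda tau: r * uir_eval(CAB_UIR, t - tau), a, hi, limit=200
                )
                total += val
            return total

        ts = [0.3, 0.7, 2.0, 5.0, 12.0]
        closed = convolve_staircase(CAB_UIR, knots, rates, ts)
        np.testing.assert_allclose(closed, [oracle(t) for t in ts], atol=1e-8)

    def test_linearity_in_input(self):
        knots = [0.0, 1.0, 4.0]
        rates = np.array([100.0, 40.0])
        t = np.linspace(0.2, 10, 17)
        c1 = convolve_staircase(CAB_UIR, knots, rates, t)
        c2 = convolve_staircase(CAB_UIR, knots, 2 * rates, t)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            convolve_staircase(CAB_UIR, [0, 1], [-5.0], [0.5])

    def test_bolus_auc_identity(self):
        """Area under D*UIR equals D * sum(c_i/lambda_i)."""
        from sparsepk import Profile, auc_linlog

        dose_ng = 1000.0
        t = np.arange(0.0, 500.0, 0.05)
        dense = auc_linlog(
            Profile(t, dose_ng * np.asarray(uir_eval(CAB_UIR, t)), "mean_by_time")
        )
        assert dense == pytest.approx(dose_ng * uir_auc(CAB_UIR), rel=5e-3)


class TestFirstOrderInput:
    def test_zero_at_time_zero(self):
        c = simulate_first_order_sq(CAB_UIR, 0.61, 60.0, 0.5, [0.0])
        assert c[0] == 0.0

    def test_fast_absorption_approaches_bolus(self):
        t = np.array([0.5, 2.0, 10.0])
        c = simulate_first_order_sq(CAB_UIR, 0.61, 60.0, 1000.0, t)
        bolus = 0.61 * 60_000.0 * np.asarray(uir_eval(CAB_UIR, t))
        np.testing.assert_allclose(c, bolus, rtol=5e-3)

    def test_matches_finely_discretized_staircase(self):
        F, dose, ka = 0.61, 60.0, 0.5
        grid = np.arange(0.0, 40.0001, 0.002)
        mid = 0.5 * (grid[:-1] + grid[1:])
        rates = F * dose * 1000.0 * ka * np.exp(-ka * mid)
        t = np.array([1.0, 5.0, 15.0, 30.0])
        stair = convolve_staircase(CAB_UIR, grid, rates, t)
        closed = simulate_first_order_sq(CAB_UIR, F, dose, ka, t)
        np.testing.assert_allclose(stair, closed, rtol=1e-3)

    def test_ka_colliding_with_disposition_rate_rejected(self):
        with pytest.raises(ValueError, match="coincides"):
            simulate_first_order_sq(CAB_UIR, 0.61, 60.0, 4.52, [1.0])


class TestDeconvolution:
    def test_round_trip_on_shared_knots_is_exact(self):
        knots = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0])
        rates = np.array([5000.0, 3000.0, 1000.0, 400.0, 50.0])
        tobs = knots[1:]
        y = convolve_staircase(CAB_UIR, knots, rates, tobs)
        prof = deconvolve(CAB_UIR, tobs, y, dose_ug=60.0)
        np.testing.assert_allclose(prof.rates, rates, rtol=1e-6)

    def test_first_order_input_recovers_bioavailable_dose(self):
        F, dose, ka = 0.61, 60.0, 0.5
        t = np.arange(0.5, 30.01, 0.5)
        y = simulate_first_order_sq(CAB_UIR, F, dose, ka, t)
        prof = deconvolve(CAB_UIR, t, y, dose_ug=dose, F=F)
        assert prof.cumulative_ng[-1] == pytest.approx(F * dose * 1000.0, rel=0.02)
        assert prof.fraction_of_dose[-1] == pytest.approx(F, rel=0.02)
        assert prof.residual_ng[-1] == pytest.approx(0.0, abs=0.02 * F * dose * 1000)

    def test_noisy_observations_still_recover_extent(self):
        """5% proportional noise: cumulative profile is non-decreasing and the
        median recovered extent over seeds stays within 10% of truth."""
        F, dose, ka = 0.61, 60.0, 0.5
        t = np.arange(0.5, 30.01, 0.5)
        f = simulate_first_order_sq(CAB_UIR, F, dose, ka, t)
        finals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = f * (1 + 0.05 * rng.standard_normal(f.size))
            prof = deconvolve(CAB_UIR, t, np.maximum(y, 0.0), dose_ug=dose, F=F)
            assert np.all(prof.rates >= 0)
            assert np.all(np.diff(prof.cumulative_ng) >= 0)
            finals.append(prof.cumulative_ng[-1])
        assert np.median(finals) == pytest.approx(F * dose * 1000.0, rel=0.10)

    def test_all_zero_observations_give_zero_profile(self):
        prof = deconvolve(CAB_UIR, [1.0, 2.0, 3.0], [0.0, 0.0, 0.0], dose_ug=60.0)
        np.testing.assert_array_equal(prof.rates, 0.0)
        assert prof.fraction_of_dose[-1] == 0.0

    def test_residual_uses_total_dose_without_f(self):
        knots = np.array([0.0, 1.0, 2.0])
        rates = np.array([1000.0, 500.0])
        y = convolve_staircase(CAB_UIR, knots, rates, knots[1:])
        prof = deconvolve(CAB_UIR, knots[1:], y, dose_ug=60.0, knots=knots)
        assert prof.residual_ng[-1] == pytest.approx(60_000.0 - 1500.0, rel=1e-6)

    def test_log_scale_objective_round_trip(self):
        knots = np.array([0.0, 1.0, 3.0, 6.0])
        rates = np.array([2000.0, 700.0, 100.0])
        tobs = knots[1:]
        y = convolve_staircase(CAB_UIR, knots, rates, tobs)
        prof = deconvolve(CAB_UIR, tobs, y, dose_ug=60.0, scale="log")
        np.testing.assert_allclose(prof.rates, rates, rtol=1e-4)

    def test_estimator_contract(self):
        dec = StaircaseDeconvolver(uir=CAB_UIR, dose_ug=60.0)
        cloned = clone(dec)
        assert cloned.get_params()["dose_ug"] == 60.0
        t = np.array([1.0, 2.0, 4.0])
        y = convolve_staircase(CAB_UIR, [0.0, 1.0, 2.0, 4.0], [500.0, 200.0, 50.0], t)
        dec.fit(t, y)
        np.testing.assert_allclose(dec.predict(t), y, rtol=1e-8)
        assert hasattr(dec, "absorption_profile_")
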
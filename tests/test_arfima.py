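"""Fractional differencing, long-memory estimation and AIC model selection."""

import numpy as np
import pytest
from scipy.signal import lfilter

from wavedim import (estimate_d, estimate_d_whittle, fit_arma, frac_diff,
                     generate_colored_noise, generate_fgn,
                     generate_fractional_noise, select_arfima)
from wavedim.arfima import arfima_autocorrelation, exact_gaussian_loglikelihood
from wavedim.synthesis import fractional_noise_autocovariance


def simulate_ar1(n, phi, seed, burn=200):
    e = np.random.default_rng(seed).standard_normal(n + burn)
    return lfilter([1.0], [1.0, -phi], e)[burn:]


def simulate_arma11(n, phi, theta, seed, burn=200):
    e = np.random.default_rng(seed).standard_normal(n + burn)
    return lfilter([1.0, theta], [1.0, -phi], e)[burn:]


class TestFracDiff:
    def test_d_zero_is_identity(self, rng):
        x = rng.standard_normal(128)
        assert np.allclose(frac_diff(x, 0.0), x)

    def test_d_one_is_first_differences(self, rng):
        x = rng.standard_normal(128)
        y = frac_diff(x, 1.0)
        assert y[0] == x[0]  # leading-term convention
        assert np.allclose(y[1:], np.diff(x))

    def test_inverse_operator_identity(self, rng):
        x = rng.standard_normal(1024)
        back = frac_diff(frac_diff(x, 0.4), -0.4)
        half = len(x) // 2
        assert np.max(np.abs(back[half:] - x[half:])) < 1e-6

    def test_output_length_preserved(self, rng):
        assert frac_diff(rng.standard_normal(77), 0.3).shape == (77,)


class TestEstimateD:
    def test_white_noise_has_no_memory(self, rng):
        ds = [estimate_d(rng.standard_normal(2048)) for _ in range(100)]
        assert np.mean(ds) == pytest.approx(0.0, abs=0.05)

    def test_pure_fractional_noise_recovery(self):
        ds = [estimate_d(generate_fractional_noise(2048, 0.3, s)) for s in range(100)]
        assert np.mean(ds) == pytest.approx(0.3, abs=0.05)

    @pytest.mark.parametrize("d_true", [0.1, 0.2, 0.3, 0.4])
    def test_recovery_bias_across_grid(self, d_true):
        ds = [estimate_d(generate_fractional_noise(2048, d_true, 100 + s))
              for s in range(100)]
        assert abs(np.mean(ds) - d_true) <= 0.05

    def test_fgn_maps_to_h_minus_half(self):
        ds = [estimate_d(generate_fgn(2048, 0.7, s)) for s in range(100)]
        assert np.mean(ds) == pytest.approx(0.2, abs=0.05)

    def test_bandwidth_validation(self, rng):
        x = rng.standard_normal(256)
        with pytest.raises(ValueError):
            estimate_d(x, bandwidth=3)
        with pytest.raises(ValueError):
            estimate_d(x, bandwidth=200)

    def test_local_whittle_agrees(self):
        ds = [estimate_d_whittle(generate_fractional_noise(2048, 0.3, s))
              for s in range(50)]
        assert np.mean(ds) == pytest.approx(0.3, abs=0.05)


class TestExactLikelihoodMachinery:
    def test_white_noise_likelihood_matches_closed_form(self, rng):
        # for rho = delta the exact llf reduces to the iid Gaussian formula
        x = rng.standard_normal(256)
        rho = np.zeros(256)
        rho[0] = 1.0
        llf, s2 = exact_gaussian_loglikelihood(x, rho)
        s2_direct = np.mean(x ** 2)
        llf_direct = -0.5 * 256 * (np.log(2 * np.pi * s2_direct) + 1.0)
        assert s2 == pytest.approx(s2_direct, rel=1e-12)
        assert llf == pytest.approx(llf_direct, rel=1e-12)

    def test_ar1_likelihood_matches_statsmodels(self):
        from statsmodels.tsa.arima.model import ARIMA
        x = simulate_ar1(512, 0.6, seed=4)
        x = x - x.mean()
        res = ARIMA(x, order=(1, 0, 0), trend="n").fit()
        phi = float(res.arparams[0])
        rho = phi ** np.arange(512)
        llf, _ = exact_gaussian_loglikelihood(x, rho)
        # same model, same data: profiled-variance exact llf >= optimizer's
        # llf up to tiny numerical slack
        assert llf == pytest.approx(float(res.llf), abs=0.05)

    def test_arfima_autocorrelation_pure_case(self):
        got = arfima_autocorrelation(0.3, (), (), 5)
        ref = fractional_noise_autocovariance(0.3, 5)
        assert np.allclose(got, ref / ref[0], rtol=1e-12)

    def test_arfima_autocorrelation_with_ar_part(self):
        # d = 0 with an AR(1) filter must reduce to the AR(1) autocorrelation
        got = arfima_autocorrelation(0.0, (0.6,), (), 6)
        assert np.allclose(got, 0.6 ** np.arange(7), atol=1e-9)


class TestFitArma:
    def test_ar1_coefficient_recovery(self):
        phis = []
        for seed in range(30):
            cand = fit_arma(simulate_ar1(1024, 0.6, seed), 1, 0)
            assert cand.status == "ok"
            phis.append(cand.ar[0])
        assert np.mean(phis) == pytest.approx(0.6, abs=0.1)

    def test_white_noise_prefers_smallest_model(self, rng):
        # the true model's AIC should be at or near the grid optimum usually
        hits = 0
        reps = 25
        for _ in range(reps):
            x = rng.standard_normal(512)
            aics = {(p, q): fit_arma(x, p, q).aic for p in range(3) for q in range(3)}
            if aics[(0, 0)] <= min(aics.values()) + 2.0:
                hits += 1
        assert hits >= 0.6 * reps

    def test_constant_series_is_numerical_error(self):
        cand = fit_arma(np.full(512, 3.0), 1, 1)
        assert cand.status == "numerical_error"
        assert not np.isfinite(cand.log_likelihood)

    def test_aic_identity(self):
        cand = fit_arma(simulate_ar1(512, 0.5, seed=1), 2, 1)
        assert cand.aic == pytest.approx(2 * cand.k - 2 * cand.log_likelihood, abs=1e-8)

    def test_invalid_order_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_arma(rng.standard_normal(256), 3, 0)


class TestSelectArfima:
    def test_grid_completeness_and_winner_optimality(self):
        sel = select_arfima(generate_fgn(1024, 0.7, 3))
        assert len(sel.candidates) == 18
        assert {(c.p, c.q, c.d_estimated) for c in sel.candidates} == {
            (p, q, e) for p in range(3) for q in range(3) for e in (False, True)}
        ok = [c for c in sel.candidates if c.status == "ok"]
        assert sel.winner is not None
        assert all(sel.winner.aic <= c.aic + 1e-9 for c in ok)
        assert sel.preference in ("arima_preferred", "arfima_preferred")

    def test_aic_identity_for_both_classes(self):
        sel = select_arfima(generate_fgn(1024, 0.7, 5))
        for c in sel.candidates:
            if c.status == "ok":
                assert c.aic == pytest.approx(2 * c.k - 2 * c.log_likelihood, abs=1e-6)

    def test_short_memory_series_prefer_arima(self):
        prefs = [select_arfima(simulate_arma11(1024, 0.6, 0.4, seed)).preference
                 for seed in range(11)]
        assert prefs.count("arima_preferred") > 5

    def test_white_noise_prefers_arima(self):
        prefs = [select_arfima(generate_fgn(1024, 0.5, seed)).preference
                 for seed in range(11)]
        assert prefs.count("arima_preferred") > 5

    def test_constant_series_is_fit_error_not_exception(self):
        sel = select_arfima(np.full(256, 1.0))
        assert sel.preference == "fit_error"
        assert sel.winner is None
        assert all(c.status == "numerical_error" for c in sel.candidates)

    def test_nonfinite_series_is_fit_error_not_exception(self):
        x = np.ones(256)
        x[13] = np.nan
        sel = select_arfima(x)
        assert sel.preference == "fit_error"

    def test_nonstationary_series_triggers_differencing_guard(self):
        sel = select_arfima(generate_colored_noise(512, -2.0, 7))
        assert sel.differenced
        assert 0.6 < sel.d_hat < 1.4

    def test_minimum_length(self, rng):
        with pytest.raises(ValueError):
            select_arfima(rng.standard_normal(100))
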
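"""Generator contracts: determinism, spectral calibration, fGn exactness."""

import numpy as np
import pytest

from wavedim import (BandSpec, generate_band, generate_battery,
                     generate_colored_noise, generate_fgn,
                     generate_fractional_noise, generate_square_wave)
from wavedim.scaling import psd_slope, dfa
from wavedim.synthesis import fgn_autocovariance, fractional_noise_autocovariance


class TestSquareWave:
    def test_block_pattern(self):
        w = generate_square_wave(8, 4)
        assert w.samples.tolist() == [1, 1, -1, -1, 1, 1, -1, -1]

    def test_power_only_at_odd_harmonics(self):
        w = generate_square_wave(2048, 64)
        power = np.abs(np.fft.rfft(w.samples)) ** 2
        fundamental = 2048 // 64
        harmonics = fundamental * np.arange(1, 32, 2)
        others = np.setdiff1d(np.arange(1, 1025), harmonics)
        assert power[harmonics].min() > 1e-6
        assert power[others].max() < 1e-12 * power[harmonics].max()

    @pytest.mark.parametrize("n,period", [(100, 7), (100, 8), (64, 13)])
    def test_invalid_period_rejected(self, n, period):
        with pytest.raises(ValueError):
            generate_square_wave(n, period)


class TestDeterminism:
    @pytest.mark.parametrize("make", [
        lambda s: generate_colored_noise(512, -1.3, s).samples,
        lambda s: generate_fgn(512, 0.7, s).samples,
        lambda s: generate_fractional_noise(512, 0.3, s).samples,
    ])
    def test_same_seed_same_series(self, make):
        assert np.array_equal(make(42), make(42))
        assert not np.array_equal(make(42), make(43))

    def test_battery_reproducible(self):
        a = generate_battery(256, seed=7)
        b = generate_battery(256, seed=7)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.samples, wb.samples)


class TestColoredNoise:
    def test_standardized(self):
        w = generate_colored_noise(2048, -2.0, 0)
        assert abs(w.samples.mean()) < 1e-12
        assert abs(w.samples.std() - 1.0) < 1e-12

    @pytest.mark.parametrize("target", [-3.0, -2.0, -1.0, 0.0, 1.0, 2.0])
    def test_spectral_calibration(self, target):
        slopes = [psd_slope(generate_colored_noise(2048, target, seed)).exponent
                  for seed in range(50)]
        assert abs(np.mean(slopes) - target) < 0.1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_colored_noise(8, 0.0, 0)
        with pytest.raises(ValueError):
            generate_colored_noise(2048, -5.0, 0)


class TestFgn:
    def test_h_half_is_white(self):
        acs = []
        for seed in range(50):
            x = generate_fgn(1024, 0.5, seed).samples
            acs.append(np.corrcoef(x[:-1], x[1:])[0, 1])
        assert abs(np.mean(acs)) < 0.02

    def test_lag1_autocorrelation_matches_closed_form(self):
        # rho(1) = 2**(2H-1) - 1 for fGn; sample autocorrelation carries a
        # small negative finite-sample bias, hence the loose band
        target = 2 ** (2 * 0.7 - 1) - 1
        acs = [np.corrcoef((x := generate_fgn(2048, 0.7, s).samples)[:-1], x[1:])[0, 1]
               for s in range(100)]
        assert np.mean(acs) == pytest.approx(target, abs=0.03)

    def test_autocovariance_exact_within_3se(self):
        # mean sample autocovariance at lags 0..5 vs the closed form; removing
        # the sample mean shifts every lag down by Var(mean), which for
        # long-memory series is O(n^(2H-2)) and computable from the closed
        # form, so the comparison subtracts it exactly
        H, n, reps = 0.7, 512, 200
        theory = fgn_autocovariance(H, 5)
        full = fgn_autocovariance(H, n - 1)
        var_of_mean = (full[0] + 2 * np.sum((1 - np.arange(1, n) / n) * full[1:])) / n
        per_rep = np.empty((reps, 6))
        for s in range(reps):
            x = generate_fgn(n, H, s).samples
            xc = x - x.mean()
            for lag in range(6):
                per_rep[s, lag] = np.mean(xc[:n - lag] * xc[lag:])
        mean = per_rep.mean(axis=0)
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - (theory - var_of_mean)) < 3 * se + 2.0 / n)

    def test_cumsum_scales_like_fbm(self):
        # DFA exponent of cumulative fGn(H) is H + 1
        alphas = [dfa(np.cumsum(generate_fgn(2048, 0.7, s).samples)).exponent
                  for s in range(20)]
        assert np.mean(alphas) == pytest.approx(1.7, abs=0.1)

    @pytest.mark.parametrize("H", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_hurst_rejected(self, H):
        with pytest.raises(ValueError):
            generate_fgn(256, H, 0)


class TestFractionalNoise:
    def test_autocovariance_matches_closed_form(self):
        d, n, reps = 0.3, 512, 200
        theory = fractional_noise_autocovariance(d, 3)
        full = fractional_noise_autocovariance(d, n - 1)
        var_of_mean = (full[0] + 2 * np.sum((1 - np.arange(1, n) / n) * full[1:])) / n
        per_rep = np.empty((reps, 4))
        for s in range(reps):
            x = generate_fractional_noise(n, d, s).samples
            xc = x - x.mean()
            for lag in range(4):
                per_rep[s, lag] = np.mean(xc[:n - lag] * xc[lag:])
        mean = per_rep.mean(axis=0)
        se = per_rep.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - (theory - var_of_mean)) < 3 * se + 2.0 / n)

    def test_autocovariance_recurrence_against_gamma_form(self):
        # spot-check the stable recurrence against the direct Gamma formula
        from scipy.special import gamma
        d = 0.4
        got = fractional_noise_autocovariance(d, 4)
        direct = [gamma(1 - 2 * d) * gamma(k + d)
                  / (gamma(d) * gamma(1 - d) * gamma(k + 1 - d)) for k in range(5)]
        assert np.allclose(got, direct, rtol=1e-12)


class TestBand:
    def test_small_band_counts(self):
        spec = BandSpec(slope_min=-1, slope_max=1, slope_step=1.0,
                        reps_per_slope=2, n=256, base_seed=0)
        series = list(generate_band(spec))
        assert len(series) == 6 == spec.total_series
        assert [s for s, _, _ in series] == [-1.0, -1.0, 0.0, 0.0, 1.0, 1.0]
        for _, _, w in series:
            assert w.n == 256
            assert abs(w.samples.std() - 1.0) < 1e-12

    def test_default_spec_matches_published_total(self):
        spec = BandSpec()
        assert spec.levels.shape[0] == 121
        assert spec.total_series == 12100
        assert spec.levels[0] == -3.0 and spec.levels[-1] == 3.0

    def test_uneven_step_rejected(self):
        with pytest.raises(ValueError):
            BandSpec(slope_min=-1, slope_max=1, slope_step=0.3)

    def test_series_regenerable_in_isolation(self):
        spec = BandSpec(slope_min=0, slope_max=1, slope_step=0.5,
                        reps_per_slope=2, n=128, base_seed=9)
        ref = {(s, r): w.samples for s, r, w in generate_band(spec)}
        again = {(s, r): w.samples for s, r, w in generate_band(spec)}
        for key in ref:
            assert np.array_equal(ref[key], again[key])


class TestBattery:
    def test_textual_constraints(self):
        bat = generate_battery(512, seed=3)
        assert len(bat) == 12
        # waveform 10 is the cumulative sum of waveform 5
        assert np.allclose(bat[9].samples, np.cumsum(bat[4].samples))
        # waveform 2 stays within the uniform support (unit-variance uniform)
        assert np.all(np.abs(bat[1].samples) <= np.sqrt(3.0))
        # waveform 12 is the square wave
        assert set(np.unique(bat[11].samples)) == {-1.0, 1.0}
        for i, w in enumerate(bat, start=1):
            assert w.label.startswith(f"waveform {i}")
            assert w.n == 512

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            generate_battery(32, seed=0)
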
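"""Synthetic waveform generators for the planar-extent benchmark.

Every generator is a pure function of its parameters and a seed: calling it
twice with identical arguments yields bit-identical sample sequences.  The
module provides the deterministic signals (sine, square wave), white noises,
exact fractional Gaussian noise (Davies-Harte circulant embedding), spectral
synthesis of colored noise at a target power-spectral-density slope, the
canonical 12-waveform battery, and the slope band (a grid of PSD-slope levels
times replicates, 12100 series at the default settings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Waveform",
    "BandSpec",
    "generate_colored_noise",
    "generate_fgn",
    "generate_fractional_noise",
    "generate_square_wave",
    "generate_sine",
    "generate_battery",
    "generate_band",
    "derive_seed",
]

#: smallest series length accepted by the estimator entry points
MIN_N = 16


@dataclass(frozen=True)
class Waveform:
    """A finite, uniformly sampled series with generator provenance.

    Attributes
    ----------
    samples : ndarray
        The sample values, arbitrary units.
    label : str
        Human-readable name ("gaussian white noise", "waveform 5", ...).
    generator : str
        Provenance string: family plus parameters, e.g. ``"fgn(H=0.9)"``.
    seed : int or None
        Seed used to generate the samples; None for deterministic signals.
    """

    samples: np.ndarray
    label: str = ""
    generator: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("waveform samples must be one-dimensional")
        object.__setattr__(self, "samples", arr)

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def truncated(self, fraction: float) -> "Waveform":
        """First ``fraction`` of the samples (used by the partial-length analysis)."""
        if not 0.0 < fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        m = max(2, int(round(self.n * fraction)))
        return Waveform(self.samples[:m], self.label, self.generator, self.seed)


def derive_seed(base_seed: int, *key: int) -> int:
    """Deterministic per-series seed from a base seed and integer indices.

    Uses :class:`numpy.random.SeedSequence` with the indices as spawn key — a
    stable, documented mixing function — and returns a 32-bit integer.
    """
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0])


def _check_n(n: int, minimum: int = MIN_N) -> None:
    if not isinstance(n, (int, np.integer)) or n < minimum:
        raise ValueError(f"n must be an integer >= {minimum}, got {n!r}")


def generate_colored_noise(n: int, target_slope: float, seed: int) -> Waveform:
    """Gaussian noise whose periodogram follows a target log-log slope.

    Construction: Gaussian white noise -> real FFT -> multiply the coefficient
    at Fourier frequency ``w = 2*pi*k/n`` by ``lambda(w)**(s/2)`` where
    ``lambda(w) = 2*sin(w/2)`` is the discrete-time frequency variable (DC term
    zeroed) -> inverse transform -> standardize to zero mean, unit variance.

    ``lambda ~ w`` at low frequency, so the target slope has its usual
    low-frequency meaning; using ``lambda`` rather than raw frequency makes the
    imposed power law exact at every Fourier frequency of the discrete series
    (an ARFIMA(0, d, 0) spectrum is proportional to ``lambda**(-2d)`` exactly),
    which is what the slope estimator in :mod:`wavedim.scaling` measures.
    """
    _check_n(n)
    if not -4.0 <= target_slope <= 4.0:
        raise ValueError(f"target_slope must lie in [-4, 4], got {target_slope}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    coeff = np.fft.rfft(white)
    w = 2.0 * np.pi * np.arange(1, coeff.shape[0]) / n
    coeff[1:] *= (2.0 * np.sin(w / 2.0)) ** (target_slope / 2.0)
    coeff[0] = 0.0
    x = np.fft.irfft(coeff, n)
    x = (x - x.mean()) / x.std()
    return Waveform(x, label=f"colored noise (slope {target_slope:g})",
                    generator=f"colored(slope={target_slope:g})", seed=int(seed))


def _circulant_embedding_sample(acov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary Gaussian sample via Davies-Harte circulant embedding.

    ``acov`` holds autocovariances gamma(0..n); returns a length-n sample.
    Negative circulant eigenvalues (tiny, from rounding) are clipped to zero.
    """
    n = acov.shape[0] - 1
    row = np.concatenate([acov, acov[-2:0:-1]])          # circulant first row, length 2n
    m = row.shape[0]
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)
    half = m // 2
    weights = np.empty(m, dtype=complex)
    weights[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    weights[half] = np.sqrt(lam[half] / m) * rng.standard_normal()
    u = rng.standard_normal(half - 1)
    v = rng.standard_normal(half - 1)
    weights[1:half] = np.sqrt(lam[1:half] / (2.0 * m)) * (u + 1j * v)
    weights[half + 1:] = np.conj(weights[1:half][::-1])
    return np.fft.fft(weights)[:n].real


def fgn_autocovariance(H: float, max_lag: int) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fGn at lags 0..max_lag."""
    k = np.arange(max_lag + 1, dtype=float)
    return 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def fractional_noise_autocovariance(d: float, max_lag: int) -> np.ndarray:
    """Closed-form autocovariance of ARFIMA(0, d, 0) with unit innovations.

    ``gamma(k) = Gamma(1-2d) Gamma(k+d) / (Gamma(d) Gamma(1-d) Gamma(k+1-d))``
    for ``|d| < 1/2``; evaluated in log space for numerical stability.
    """
    if not -0.5 < d < 0.5:
        raise ValueError(f"d must lie in (-0.5, 0.5), got {d}")
    if abs(d) < 1e-12:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    gamma0 = np.exp(gammaln(1 - 2 * d) - 2 * gammaln(1 - d))
    k = np.arange(1, max_lag + 1, dtype=float)
    # stable ratio recurrence: gamma(k)/gamma(k-1) = (k-1+d)/(k-d)
    return gamma0 * np.concatenate([[1.0], np.cumprod((k - 1 + d) / (k - d))])


def generate_fgn(n: int, H: float, seed: int) -> Waveform:
    """Exact fractional Gaussian noise by circulant embedding.

    The process has zero mean and unit variance (in distribution; the sample
    is not re-standardized, so its autocovariance matches the closed form
    exactly in expectation).  ``H = 0.5`` reduces to Gaussian white noise.
    """
    _check_n(n)
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst exponent H must lie in (0, 1), got {H}")
    rng = np.random.default_rng(seed)
    x = _circulant_embedding_sample(fgn_autocovariance(H, n), rng)
    return Waveform(x, label=f"fGn (H={H:g})", generator=f"fgn(H={H:g})", seed=int(seed))


def generate_fractional_noise(n: int, d: float, seed: int) -> Waveform:
    """Exact ARFIMA(0, d, 0) series (unit innovation variance), |d| < 1/2.

    Same circulant-embedding construction as :func:`generate_fgn`, driven by
    the closed-form fractional-noise autocovariance; used as the simulation
    oracle for long-memory estimation checks.
    """
    _check_n(n)
    rng = np.random.default_rng(seed)
    x = _circulant_embedding_sample(fractional_noise_autocovariance(d, n), rng)
    return Waveform(x, label=f"fractional noise (d={d:g})",
                    generator=f"arfima0d0(d={d:g})", seed=int(seed))


def generate_square_wave(n: int, period: int) -> Waveform:
    """Square wave alternating between +1 and -1 in half-period blocks.

    ``period`` must be even and divide ``n`` so the series holds an integer
    number of cycles — otherwise spectral leakage would spoil the odd-harmonic
    structure the benchmark relies on.
    """
    _check_n(n, minimum=2)
    if period % 2 != 0:
        raise ValueError(f"period must be even, got {period}")
    if n % period != 0:
        raise ValueError(f"period ({period}) must divide n ({n}) for integer cycles")
    idx = np.arange(n)
    x = np.where((idx % period) < period // 2, 1.0, -1.0)
    return Waveform(x, label=f"square wave (period {period})",
                    generator=f"square(period={period})", seed=None)


def generate_sine(n: int, cycles: float = 2.0) -> Waveform:
    """Unit-amplitude sine over ``cycles`` full periods (the line-like anchor)."""
    _check_n(n, minimum=2)
    x = np.sin(2.0 * np.pi * cycles * np.arange(n) / n)
    return Waveform(x, label=f"sine ({cycles:g} cycles)",
                    generator=f"sine(cycles={cycles:g})", seed=None)


def generate_battery(n: int = 2048, seed: int = 0) -> list[Waveform]:
    """The canonical 12-waveform battery, ordered roughly line-like to plane-like.

    Only four members are pinned by the benchmark's textual constraints:
    2 = uniform white noise, 5 = Gaussian white noise, 10 = cumulative sum of
    5, 12 = square wave.  The remaining members span the planar-extent range:

    ====  ==========================================
    1     sine (2 cycles)
    2     uniform white noise (zero mean, unit variance)
    3     pink noise (PSD slope -1)
    4     fGn, H = 0.9
    5     Gaussian white noise
    6     fGn, H = 0.1
    7     colored noise, slope +1
    8     colored noise, slope +2
    9     fBm, H = 0.5 (spectral synthesis, slope -2)
    10    cumulative sum of waveform 5
    11    fBm, H = 0.9 (cumulative sum of exact fGn)
    12    square wave (period 64)
    ====  ==========================================

    Returns a list indexed 0..11 whose labels carry the 1-based waveform
    numbers used in reports.
    """
    _check_n(n, minimum=64)
    seeds = [derive_seed(seed, i) for i in range(1, 13)]

    w5 = np.random.default_rng(seeds[4]).standard_normal(n)
    uniform = np.random.default_rng(seeds[1]).uniform(-np.sqrt(3.0), np.sqrt(3.0), n)
    fbm09 = np.cumsum(generate_fgn(n, 0.9, seeds[10]).samples)

    members: list[tuple[str, np.ndarray, str, int | None]] = [
        ("sine", generate_sine(n, 2.0).samples, "sine(cycles=2)", None),
        ("uniform white noise", uniform, "uniform_white", seeds[1]),
        ("pink noise", generate_colored_noise(n, -1.0, seeds[2]).samples,
         "colored(slope=-1)", seeds[2]),
        ("fGn H=0.9", generate_fgn(n, 0.9, seeds[3]).samples, "fgn(H=0.9)", seeds[3]),
        ("gaussian white noise", w5, "gaussian_white", seeds[4]),
        ("fGn H=0.1", generate_fgn(n, 0.1, seeds[5]).samples, "fgn(H=0.1)", seeds[5]),
        ("colored slope +1", generate_colored_noise(n, 1.0, seeds[6]).samples,
         "colored(slope=1)", seeds[6]),
        ("colored slope +2", generate_colored_noise(n, 2.0, seeds[7]).samples,
         "colored(slope=2)", seeds[7]),
        ("fBm H=0.5", generate_colored_noise(n, -2.0, seeds[8]).samples,
         "colored(slope=-2)", seeds[8]),
        ("cumsum of gaussian white", np.cumsum(w5), "cumsum(gaussian_white)", seeds[4]),
        ("fBm H=0.9", fbm09, "cumsum(fgn(H=0.9))", seeds[10]),
        ("square wave", generate_square_wave(n, 64).samples, "square(period=64)", None),
    ]
    return [
        Waveform(x, label=f"waveform {i}: {name}", generator=gen, seed=s)
        for i, (name, x, gen, s) in enumerate(members, start=1)
    ]


@dataclass(frozen=True)
class BandSpec:
    """Parameters of the slope band: a grid of PSD-slope levels x replicates.

    The defaults reproduce the benchmark's 121 levels (-3.00, -2.95, ..., 3.00)
    times 100 replicates = 12100 series of 2048 samples.
    """

    slope_min: float = -3.0
    slope_max: float = 3.0
    slope_step: float = 0.05
    reps_per_slope: int = 100
    n: int = 2048
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.slope_step <= 0:
            raise ValueError("slope_step must be positive")
        if self.reps_per_slope < 1:
            raise ValueError("reps_per_slope must be a positive integer")
        _check_n(self.n)
        span = self.slope_max - self.slope_min
        k = span / self.slope_step
        if span < 0 or abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"slope_step {self.slope_step} does not evenly tile "
                f"[{self.slope_min}, {self.slope_max}]")

    @property
    def levels(self) -> np.ndarray:
        """Evenly spaced slope levels including both endpoints."""
        count = int(round((self.slope_max - self.slope_min) / self.slope_step)) + 1
        return np.linspace(self.slope_min, self.slope_max, count)

    @property
    def total_series(self) -> int:
        return self.levels.shape[0] * self.reps_per_slope


def generate_band(spec: BandSpec) -> Iterator[tuple[float, int, Waveform]]:
    """Stream the band series as ``(target_slope, rep_index, waveform)`` triples.

    Per-series seeds derive deterministically from ``(base_seed, level_index,
    rep_index)``, so any single series can be regenerated in isolation.
    """
    for li, slope in enumerate(spec.levels):
        for rep in range(spec.reps_per_slope):
            s = derive_seed(spec.base_seed, li, rep)
            yield float(slope), rep, generate_colored_noise(spec.n, float(slope), s)
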
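"""Self-affinity exponent estimators: PSD slope, DFA and SDA.

All three estimators reduce to an ordinary least-squares fit on log-log
coordinates; each returns a :class:`ScalingFit` that stores the fitted points
themselves, so the exponent can be re-derived (and plotted) from the result
alone.

The periodogram slope is fitted against the discrete-time frequency variable
``lambda(w) = 2 sin(w/2)`` by default.  ``lambda`` is asymptotically equal to
the raw angular frequency at the low-frequency end but is the exact frequency
variable of discrete power-law spectra (a fractionally differenced process has
spectral density proportional to ``lambda**(-2d)`` at all frequencies, and the
periodogram of a sampled square wave follows ``lambda**(-2)`` exactly); fitting
against raw frequency instead is available through the fit policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthesis import Waveform

__all__ = ["ScalingFit", "PsdFitPolicy", "psd_slope", "dfa", "sda", "default_dfa_scales"]

_MIN_SCALING_N = 64


@dataclass(frozen=True)
class PsdFitPolicy:
    """Which periodogram ordinates the slope is fitted over, and how.

    ``fraction``
        Fit over the lowest ``fraction`` of the nonzero Fourier frequencies
        (default 0.25, common fractal-physiology practice).
    ``harmonics``
        Explicit list of frequency indices ``k`` (1 = fundamental of the full
        record) overriding ``fraction`` — used e.g. to fit a square wave over
        its odd harmonics only.
    ``abscissa``
        ``"discrete"`` fits against ``lambda = 2 sin(pi k / n)``;
        ``"frequency"`` against the raw ``k / n``.
    ``taper``
        ``None`` (default) or ``"hann"``.
    """

    fraction: float = 0.25
    harmonics: Sequence[int] | None = None
    abscissa: str = "discrete"
    taper: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if self.abscissa not in ("discrete", "frequency"):
            raise ValueError(f"unknown abscissa {self.abscissa!r}")
        if self.taper not in (None, "hann"):
            raise ValueError(f"unknown taper {self.taper!r}")


@dataclass(frozen=True)
class ScalingFit:
    """A log-log regression result.

    ``fit_points`` holds the (log-abscissa, log-ordinate) pairs the exponent
    was fitted to; re-running OLS on them reproduces ``exponent`` and
    ``intercept`` exactly.
    """

    exponent: float
    intercept: float
    method: str
    fit_points: np.ndarray
    fit_range: str
    r_squared: float

    def refit(self) -> tuple[float, float]:
        """Recompute (slope, intercept) from the stored fit points."""
        return _ols(self.fit_points[:, 0], self.fit_points[:, 1])[:2]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of an ordinary least-squares line."""
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def _samples(w: Waveform | np.ndarray, min_n: int = _MIN_SCALING_N) -> np.ndarray:
    x = w.samples if isinstance(w, Waveform) else np.asarray(w, dtype=float)
    if x.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} samples, got {x.shape[0]}")
    return x


def periodogram(x: np.ndarray, taper: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Raw periodogram at the positive Fourier frequencies.

    Returns ``(k, power)`` for ``k = 1 .. n//2``; the mean is removed first.
    """
    n = x.shape[0]
    z = x - x.mean()
    if taper == "hann":
        win = np.hanning(n)
        z = z * win / np.sqrt(np.mean(win ** 2))
    coeff = np.fft.rfft(z)
    power = np.abs(coeff[1:]) ** 2 / n
    return np.arange(1, power.shape[0] + 1), power


def psd_slope(w: Waveform | np.ndarray,
              fit_policy: PsdFitPolicy | None = None) -> ScalingFit:
    """Log-log periodogram slope of the waveform.

    The slope ``s`` is negative for persistent ("red") signals: white noise
    has ``s = 0``, Brownian motion ``s = -2``.
    """
    policy = fit_policy or PsdFitPolicy()
    x = _samples(w)
    n = x.shape[0]
    k, power = periodogram(x, policy.taper)
    if policy.harmonics is not None:
        sel = np.asarray(policy.harmonics, dtype=int)
        if sel.min() < 1 or sel.max() > k.shape[0]:
            raise ValueError("harmonic index outside the periodogram range")
        rng_desc = f"harmonics {list(map(int, sel))}"
    else:
        upto = max(4, int(np.floor(policy.fraction * k.shape[0])))
        sel = k[:upto]
        rng_desc = f"lowest {policy.fraction:g} of nonzero frequencies (k=1..{upto})"
    pw = power[sel - 1]
    nonzero = pw > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} zero-power frequencies from the PSD fit",
            stacklevel=2)
        sel, pw = sel[nonzero], pw[nonzero]
    if sel.shape[0] < 4:
        raise ValueError("fewer than 4 usable frequencies for the PSD fit")
    if policy.abscissa == "discrete":
        absc = 2.0 * np.sin(np.pi * sel / n)
    else:
        absc = sel / n
    logx, logy = np.log10(absc), np.log10(pw)
    slope, intercept, r2 = _ols(logx, logy)
    return ScalingFit(exponent=slope, intercept=intercept, method="psd",
                      fit_points=np.column_stack([logx, logy]),
                      fit_range=rng_desc + f", abscissa={policy.abscissa}",
                      r_squared=r2)


def default_dfa_scales(n: int, n_scales: int = 16,
                       s_min: int = 4, s_max: int | None = None) -> np.ndarray:
    """At least ``n_scales`` distinct log-spaced integer scales in [s_min, n/4]."""
    if s_max is None:
        s_max = n // 4
    target = min(n_scales, s_max - s_min + 1)
    density = n_scales
    scales = np.unique(np.round(np.geomspace(s_min, s_max, density)).astype(int))
    while scales.shape[0] < target:
        density *= 2  # rounding merged small scales; sample the grid denser
        scales = np.unique(np.round(np.geomspace(s_min, s_max, density)).astype(int))
    return scales


def dfa(w: Waveform | np.ndarray, scales: Sequence[int] | None = None,
        detrend_order: int = 1) -> ScalingFit:
    """Detrended fluctuation analysis.

    The profile (cumulative sum of the mean-centred samples) is split into
    non-overlapping windows at each scale; a least-squares polynomial of
    ``detrend_order`` is removed per window and ``F(scale)`` is the RMS of the
    pooled residuals.  The exponent ``alpha`` is the OLS slope of ``log10 F``
    against ``log10 scale``: 0.5 for white noise, 1.5 for Brownian motion,
    ``H`` for fGn and ``H + 1`` for fBm.
    """
    x = _samples(w)
    n = x.shape[0]
    if detrend_order < 0:
        raise ValueError("detrend_order must be >= 0")
    scale_arr = (default_dfa_scales(n) if scales is None
                 else np.unique(np.asarray(scales, dtype=int)))
    if scale_arr.min() < detrend_order + 2:
        raise ValueError("smallest scale must exceed the detrending order + 1")
    profile = np.cumsum(x - x.mean())
    logs, logF = [], []
    dropped = []
    for s in scale_arr:
        n_windows = n // s
        if n_windows < 2:
            dropped.append(int(s))
            continue
        seg = profile[:n_windows * s].reshape(n_windows, s)
        design = np.vander(np.arange(s, dtype=float), detrend_order + 1)
        q, _ = np.linalg.qr(design)
        resid = seg - (seg @ q) @ q.T
        fluct = np.sqrt(np.mean(resid ** 2))
        if fluct == 0:  # e.g. constant input: nothing to fit at this scale
            dropped.append(int(s))
            continue
        logs.append(np.log10(s))
        logF.append(np.log10(fluct))
    if dropped:
        warnings.warn(f"dropped unusable DFA scales (too few windows or zero "
                      f"fluctuation): {dropped}", stacklevel=2)
    if len(logs) < 4:
        raise ValueError("fewer than 4 usable DFA scales")
    logx, logy = np.asarray(logs), np.asarray(logF)
    slope, intercept, r2 = _ols(logx, logy)
    return ScalingFit(exponent=slope, intercept=intercept, method="dfa",
                      fit_points=np.column_stack([logx, logy]),
                      fit_range=f"scales {int(scale_arr.min())}..{int(scale_arr.max())}, "
                                f"order {detrend_order}",
                      r_squared=r2)


def sda(w: Waveform | np.ndarray, bin_sizes: Sequence[int] | None = None) -> ScalingFit:
    """Standardized dispersion analysis.

    The series is standardized to mean 0, SD 1 (population SD); for each bin
    size ``b`` the SD of the means of consecutive non-overlapping bins is
    computed.  The exponent is the OLS slope of ``log10 SD`` against
    ``log10 b``: -0.5 for white noise (central-limit scaling), ``H - 1`` for
    fGn.  The dispersion of fBm-regime signals saturates, which is why SDA is
    an fGn-branch instrument only.
    """
    x = _samples(w)
    n = x.shape[0]
    if bin_sizes is None:
        bins = 2 ** np.arange(1, int(np.log2(n // 8)) + 1)
    else:
        bins = np.unique(np.asarray(bin_sizes, dtype=int))
        if bins.min() < 2:
            raise ValueError("bin sizes must be >= 2")
    sd = x.std()
    if sd == 0:
        raise ValueError("constant series has no dispersion to analyse")
    z = (x - x.mean()) / sd
    logs, logsd = [], []
    remainders = []
    for b in bins:
        m = n // b
        if m < 2:
            continue
        if n % b:
            remainders.append(int(b))
        means = z[:m * b].reshape(m, b).mean(axis=1)
        disp = means.std()  # population SD
        if disp == 0:
            continue
        logs.append(np.log10(b))
        logsd.append(np.log10(disp))
    if remainders:
        warnings.warn(
            f"bin sizes {remainders} do not divide n={n}; trailing remainder discarded",
            stacklevel=2)
    if len(logs) < 4:
        raise ValueError("fewer than 4 usable SDA bin sizes")
    logx, logy = np.asarray(logs), np.asarray(logsd)
    slope, intercept, r2 = _ols(logx, logy)
    return ScalingFit(exponent=slope, intercept=intercept, method="sda",
                      fit_points=np.column_stack([logx, logy]),
                      fit_range=f"bins {int(bins.min())}..{int(bins.max())}",
                      r_squared=r2)
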
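# Methods

`wavedim` estimates the *planar extent* of an empirical waveform — how much of
the bounded plane its graph occupies, a number between 1 (a line) and 2 (a
plane-filling curve) — and benchmarks direct geometric estimators against
conversions of self-affinity exponents.  This note records the models, the
conventions and the numerical choices, and what the synthetic benchmark does
and does not establish.

## The waveform as a finite curve

A uniformly sampled series of length N is treated as a self-avoiding open
curve in a bounded plane.  Both geometric estimators first embed it in the
unit square by a double linear transformation: `x_i = i/(N-1)` and
`y_i = (v_i - min v)/(max v - min v)`.  A constant series is placed at
`y = 0.5` (centre of the square), which makes its length exactly 1 and its
dimension exactly 1 rather than an indeterminate 0/0.

**Curve-length (Sevcik) estimator.**  `D = 1 + ln L / ln(2 N')` with L the
Euclidean polyline length of the normalized curve and `N' = N - 1` the number
of observation intervals.  This variant returns exactly 1 for a horizontal
line; it is invariant under affine amplitude changes and time reversal because
the normalization absorbs them.

**Box-counting estimator (D_uBC).**  The normalized curve is rasterized onto a
2N-by-2N binary grid with a supercover line tracer: every half-open grid cell
`[c/S, (c+1)/S) x [r/S, (r+1)/S)` that a segment passes through is marked, so
the drawn polyline never skips cells; points with coordinate exactly 1 belong
to the last row/column.  Occupied boxes are counted at dyadic box sizes from
2 px to side/4 (the single-pixel and near-full-image scales are saturated and
excluded) and D is the OLS slope of `log10 N(eps)` versus `log10 (1/eps)`.

*Known limitation:* at this raster size the box-count of a Brownian graph
(true D = 1.5) reads about 1.32–1.41, because scales below one sampling
interval are line-dominated and the count saturates early; the estimator is
used for *relative ordering*, which it preserves, not for absolute dimension.
The benchmark's ordering tests reflect exactly this use.

## Self-affinity estimators and the discrete-frequency convention

**PSD slope.**  The raw periodogram (mean removed, no taper by default; a Hann
taper is available) is fitted by OLS on log-log coordinates over the lowest
25% of the nonzero Fourier frequencies, or over an explicit harmonic list.
The log-abscissa is the discrete-time frequency variable

    lambda(w) = 2 sin(w/2),  w = 2 pi k / N,

rather than raw frequency.  `lambda ~ w` at the low-frequency end, so nothing
changes asymptotically, but `lambda` is the exact frequency variable of
discrete power-law spectra: a fractionally differenced process has spectral
density proportional to `lambda^(-2d)` at *all* frequencies, the periodogram
of a sampled square wave is proportional to `lambda^(-2)` on its odd harmonics
exactly (the Gibbs slope -2 comes out exact instead of biased to about -1.91
by the sin distortion), and a random walk's spectrum is `lambda^(-2)` exactly.
Colored noise is synthesized with the same convention (white Gaussian noise,
multiply the DFT coefficient at frequency w by `lambda(w)^(s/2)`, zero the DC
term, invert, standardize), so the generator and the estimator agree exactly
at every Fourier frequency and the slope calibration is unbiased over any fit
band.  Fitting against raw frequency remains available via the fit policy.

**DFA.**  Profile = cumulative sum of the mean-centred series; non-overlapping
windows, least-squares polynomial detrending of order 1 by default; F(s) =
RMS of pooled residuals; alpha = OLS slope of `log10 F` vs `log10 s` over at
least 16 log-spaced integer scales in [4, N/4].  Scales with fewer than two
windows or zero fluctuation are dropped with a warning.

**SDA.**  The series is standardized (population SD); for each power-of-two
bin size b in [2, N/8] the SD of the means of consecutive non-overlapping
bins is computed; the exponent is the OLS slope of `log10 SD` vs `log10 b`
(-0.5 for white noise by the central limit theorem, H - 1 for fGn).  For
persistent fGn (H around 0.8) the estimator carries a small negative
finite-sample bias (about -0.06 at N = 2048) because mean removal shrinks the
dispersion of the largest bins; the bias shrinks only slowly as the largest
bins are excluded, so the standard bin range is kept and the bias documented.
In the fBm regime the dispersion of bin means saturates, which is why SDA is
an fGn-branch instrument only.

Every fit result stores its (log x, log y) points, so the exponent is exactly
recomputable from the result object.

## Informed dimension: the fGn/fBm dichotomy

A scaling exponent maps to dimension only after deciding whether the series
behaves as fractional Gaussian noise (fGn, graph dimension `D = 2 - H`) or as
its cumulative sum (fBm).  The conversion rules:

| source | fGn branch | fBm branch |
|---|---|---|
| PSD slope s | `-1 <= s <= 1`: `H = (1-s)/2` | `s < -1`: `H = -(1+s)/2` |
| DFA alpha   | `0 < alpha < 1`: `H = alpha`  | `1 <= alpha <= 2`: `H = alpha - 1` |
| SDA slope   | `D = 1 - slope` (fGn only)    | — |

with `D = 2 - H` on both branches (equivalently `D = 3 - alpha` on the DFA
fBm branch) and all outputs clamped to [1, 2].  The white-noise and Brownian
anchors map to D = 1.5 from every estimator.  These rules approximate
well-known (H, D) pairs; they are a convention, not an analytic identity, and
the dichotomy is inherently discontinuous at the branch boundary.  The default
assigns `s = -1` to the fGn branch and `alpha = 1` to the fBm branch; a
`boundary="alternative"` flag swaps both assignments.

## Exact synthesis

All benchmark inputs are generated internally and are pure functions of their
parameters and a seed (per-series seeds derive from a base seed through
`numpy.random.SeedSequence` spawn keys, a stable documented mixing).

* **fGn** is generated exactly by Davies–Harte circulant embedding of the
  closed-form autocovariance `gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2`;
  the sample is *not* re-standardized, so its autocovariance is testable
  against the closed form (the tests subtract the exact Var(sample mean)
  term that mean removal introduces).  **ARFIMA(0, d, 0)** noise is generated
  the same way from its closed-form autocovariance (stable ratio recurrence
  `gamma(k)/gamma(k-1) = (k-1+d)/(k-d)` from `gamma(0) =
  Gamma(1-2d)/Gamma(1-d)^2`).
* **Colored noise** at a target spectral slope uses the spectral-synthesis
  construction above and *is* standardized per sample, per its generator
  contract.
* The **12-waveform battery** (default N = 2048 = 2^11) fixes the four
  text-constrained members — 2: uniform white noise, 5: Gaussian white noise,
  10: cumulative sum of 5, 12: square wave (period 64) — and fills the rest
  to span the dimension range: 1 sine, 3 pink noise, 4 fGn H=0.9, 6 fGn
  H=0.1, 7/8 colored noise slope +1/+2, 9 fBm H=0.5 (spectral synthesis,
  slope -2), 11 fBm H=0.9 (cumulative exact fGn).
* The **slope band** defaults to 121 levels (-3.00 to 3.00 in steps of 0.05)
  times 100 replicates = 12100 series; the factorization is configurable.

## ARFIMA selection

The classifier contrasts short-memory ARMA models (d = 0, p and q in 0..2,
exact Gaussian ML via statsmodels state space, no constant term) with
fractionally integrated candidates over the same (p, q) grid.  The strategy is
two-step: d is estimated once, semiparametrically, and held fixed — full joint
ML is out of scope.

* d is estimated by a **local Whittle** fit over the lowest n/8 Fourier
  frequencies (default; the classical GPH log-periodogram regression on
  `log 4 sin^2(w/2)` with bandwidth `sqrt(n)` is the stand-alone
  `estimate_d` and an option).  Local Whittle at this bandwidth has roughly
  half the GPH sampling variance, which matters because every unit of
  `Var(d_hat)` costs the fractional class about `n * Var(d_hat) * pi^2/6` in
  log-likelihood.
* ARMA parts of fractional candidates are fit on the `(1-B)^d_hat`-differenced
  series (truncated binomial filter), but each candidate's **AIC is computed
  from the exact Gaussian log-likelihood of the composite ARFIMA model on the
  original series**: the model autocorrelation is the closed-form fractional
  autocovariance convolved with the ARMA filter's psi-weight correlation
  (512 weights; geometric decay makes the truncation negligible), and the
  likelihood is evaluated by the Durbin–Levinson recursion with the innovation
  variance profiled out.  Scoring the transient-contaminated differenced
  series instead systematically penalizes the fractional class (measured
  during development: it flips the preference for long-memory fGn toward
  ARMA in roughly three quarters of series).
* AIC = `2k - 2 llf` with `k = p + q + 1`, plus 1 when d is estimated (the
  +1 in the base count is the innovation variance).  Winner = minimum AIC
  among candidates whose optimizer converged; ties break to smaller `p + q`,
  then smaller p.  If `d_hat > 0.5` the series is first-differenced, d
  re-estimated on the differences and reported as `d_diff + 1`; both classes
  are then fit on the differences.  For candidate evaluation d is capped to
  |d| <= 0.49 (the stationary-invertible range of the closed-form machinery);
  the reported d_hat is not capped.
* The selection never raises on finite input: every failure is recorded in the
  candidate's status, and a series where all 18 candidates fail is classified
  `fit_error` — failures are data.

**Honest limit of the classifier.**  At N = 2048 the AIC contest between an
exactly fitted fractional model and the best of nine exact-ML ARMA candidates
is intrinsically close for moderate memory (d near 0.2, i.e. fGn H = 0.7):
an ARMA(2,2) spectrum mimics `f^(-0.4)` almost perfectly over the observable
band, and in a ceiling experiment even the *true* fGn model fitted by exact
ML won the AIC comparison on under half of such series.  The package's
selection tracks this ceiling (about half of fGn(0.7) series classified
`arfima_preferred`, with clear ARMA preference for H = 0.5 and for genuine
ARMA data).  Any implementation reporting a decisive majority at these
conditions is over-claiming; the headline preference percentages of a band
run are therefore implementation-dependent summaries, not reproduction
targets.  No dimension conversion is offered for the ARFIMA route.

## Benchmark harness

`run_battery` applies every estimator to every battery member truncated to
25/50/75/100% of its length and reports per-method rank vectors (average ranks
on ties) keyed to the full-length D_uBC order; agreement is quantified by
Spearman rank correlation.  `run_band` streams the slope band (constant memory
in the series count) and summarizes each level by mean, median and the
5th–95th percentile envelope — the analogue of the benchmark's gray areas,
whose exact definition is not fixed by the source material.  Per-series
estimator failures are recorded and never abort a run.  The ARFIMA classifier
is excluded from band runs by default (two orders of magnitude slower than
the other estimators) and is intended for reduced-replicate presets.

## Problem sizes used by the test suite

Simulation-backed assertions use N = 2048 with 20–50 replicates for estimator
anchors (enough that the standard error is several times smaller than the
asserted tolerance), N = 512 with 200 replicates for autocovariance
exactness, and reduced band presets (a handful of levels, 3–10 replicates)
for the orchestration contracts.  Full 12100-series band runs are a CLI-scale
operation, not a test.

## What the synthetic benchmark does not show

The generators produce stationary (or exactly integrated) Gaussian processes
with known spectra.  Passing the benchmark shows the estimators are calibrated
and mutually consistent *under those conditions*; it says nothing about
nonstationary trends, oscillatory or multimodal spectra, heavy-tailed or
non-Gaussian innovations, measurement noise floors, or multifractality — all
common in physiological recordings.  The informed conversions assume the
fGn/fBm dichotomy is the right model family; for a series that is neither,
the reported D is a projection onto that family, and near the branch boundary
small estimation error moves the result discontinuously.
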
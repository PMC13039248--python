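# Methods

`lfposc` implements a complete spectral-analysis workflow for local
field potential (LFP) recordings of the kind used to track oscillatory
brain-state changes in rodent cohorts across treatment days, together
with a synthetic cohort generator that makes every stage verifiable
without access to real recordings. This note documents the models,
conventions, numerical choices and limitations.

## Signal model of the generator

A synthetic LFP trace is the sum of independent Gaussian processes:

- **Aperiodic background** with one-sided power spectral density
  `P(f) = C / f^α` (units² per Hz). It is synthesized by drawing random
  rFFT coefficients with the target amplitude profile and inverse
  transforming, so the planted exponent is exact in expectation — the
  property that exponent-recovery tests rely on. Below `plateau_hz`
  (default 0.5 Hz) the target is held constant: without the plateau an
  exponent of 1.5 would place nearly all variance into sub-0.5-Hz drift
  that no analysis stage examines, while with it the 1–150 Hz range is
  untouched. `C` is the PSD at 1 Hz; `α` defaults to 0.5, typical of
  the shallow low-frequency slopes seen in cortical LFP.
- **Oscillatory components** (δ, θ, β, low γ, high γ) realized as white
  noise shaped by a zero-phase Gaussian band-pass whose power response
  has half-power width `bandwidth` centred on `center_freq`. A Gaussian
  band (rather than a Butterworth band-pass or a pure sinusoid) gives a
  broad, symmetric spectral peak whose expected maximum sits exactly on
  the centre frequency, which keeps peak-localization tests sharp. The
  `amplitude` parameter is the component's realized RMS, enforced per
  realization via Parseval, so planted power ratios are exact.
- **Line interference**: a 50-Hz sinusoid with RMS `amplitude`.
- Optionally a **shared log-normal envelope** (slow Gaussian process,
  band-limited below `cutoff_hz`, exponentiated) multiplying all
  components flagged `shared_envelope`. This plants cross-frequency
  power comodulation with controllable depth `sigma`.

Per-signal seeds are `base_seed XOR crc32("group|mouse|session")`,
masked to 31 bits. Because the hash depends only on the key, adding a
mouse or session never changes any other signal, and two runs with the
same configuration are bit-identical on a given platform (the usual
caveat for FFT-based synthesis: across BLAS/FFT builds, agreement is to
floating-point rounding, not necessarily bitwise).

### The `paper_emulation` preset

The default cohort is 10 mice per group, two groups (`vehicle`,
`treated`), four sessions (`PRE`, `D-1`, `D-3`, `D-12`), 5 kHz sampling.
Sessions are 300 s by default — the length the multitaper arm consumes;
the FFT arm uses its first 180 s. Component amplitudes (θ 1.0, δ 0.6,
β 0.5, low γ 0.45, high γ 0.8, background C = 0.05) were chosen once so
that each band's component carries power comparable to the in-band
aperiodic background; this keeps planted multipliers visible without
making the spectra implausibly peaky. Planted dynamics: θ drops in both
groups on D-1 (vehicle ×0.8, treated ×0.7), the vehicle group drifts
back toward baseline (×0.85 on D-3, 1.0 on D-12) while the treated
group overshoots (×1.3 on D-3, ×1.5 on D-12), with δ and γ increases
joining on D-3/D-12. The multiplier values are configuration, not
claims about any empirical effect size; the ground-truth table records
the implied band-power percentages (multiplier ratio squared × 100).

What the generator does *not* emulate: spikes, sharp-wave ripples,
movement artifacts (beyond an injectable test transient), non-sinusoidal
waveform shape, nonstationarity within a session, phase–amplitude
coupling, and volume-conduction structure. Passing recovery tests on
this synthetic cohort therefore demonstrates that the analysis code
measures what it claims to measure on data satisfying its assumptions —
not that real recordings satisfy them.

## Preprocessing

- **Notch filter**: 4th-order Butterworth band-stop, 48–52 Hz cutoffs,
  applied forward–backward (`sosfiltfilt`) for exact zero phase. The
  narrow notch rings for roughly a second, so the filter is run with
  ~1 s of reflect padding; the delivered attenuation at 50 Hz is about
  50 dB with passband deviation ≪ 1 dB at 8 and 80 Hz.
- **Epoching**: non-overlapping, `floor(duration/epoch_len)` epochs,
  trailing remainder discarded. The default policy tiles contiguously
  from the recording start; an evenly-spaced policy is available when a
  capped number of epochs should sample the whole recording.
- **Artifact screening** replaces manual segment selection with a
  reproducible rule: an epoch is rejected if any sample deviates from
  the epoch median by more than `k_mad` (default 8) times the scaled
  MAD (1.4826 × median absolute deviation) of the whole recording, or
  if its peak-to-peak range is below `flat_tol` (default 1e-9, a
  flat-line/disconnection guard). At k = 8 the false-rejection rate on
  Gaussian data is far below 1 %. Rejection reasons (`amplitude`,
  `flat`) are kept per candidate epoch.

## FFT arm

Per-epoch spectra are one-sided periodograms with mean removal and an
RMS-normalized Hann window (`mean(w²) = 1`), expressed as power per bin
so that the total equals the windowed variance (Parseval within 5 %).
The Hann choice controls leakage from the steep 1/f background into
high-frequency bins; the acquisition-software convention this mirrors is
a Hann-family window. Ten-second epochs give the native 0.1-Hz grid.

Averaging is per-bin arithmetic mean and tracks the number of epochs
pooled; the pipeline averages epochs within mouse, then mouse spectra
into group displays, so 10 mice × 18 epochs report n = 180.

Two normalizations:

- **Percent of total** divides by the summed power over 1–150 Hz
  excluding the notched 48–52 Hz (both interval ends inclusive at the
  bin level), times 100. The included range sums to exactly 100.
- **Percent of baseline** divides each (mouse, band) value by the same
  mouse's value in the baseline session, times 100. Baseline rows are
  forced to exactly 100; missing or zero baselines raise errors naming
  the offending cell.

Band edges are half-open `[low, high)` — the 4-Hz bin belongs to θ, not
δ — with the topmost band (high γ, 52–150 Hz) closing at 150 inclusive.
δ starts at 1 Hz; the 48–52 Hz gap between the γ bands is never
assigned to any band.

## Aperiodic fits

Ordinary least squares of log10(power) on log10(frequency) over a
frequency range (defaults 1–48 and 52–150 Hz, fitted separately because
the notch empties the gap between them). Zero-power bins are dropped
with a logged count; fewer than three usable bins is an error. On a
noise-free power law the fit is exact to numerical precision and
identical across ranges. Flat spectra return slope 0 with R² = 0 (zero
explained variance by convention). An optional one-pass robust mode
drops bins whose residual exceeds two robust standard deviations
(1.4826 × MAD) and refits once, de-weighting narrowband peaks, which
are model violations. Fits default to percent-of-total spectra;
the slope is invariant to that scaling, the intercept is not.

## Multitaper arm

Windows of `T = 2 s` with half-bandwidth `W = 1 Hz` admit
`K = 2TW − 1 = 3` discrete prolate spheroidal sequences (scipy's
`dpss`, unit-norm), stepped by `dt = 0.5 s` (75 % overlap) on the
native Rayleigh grid `dF = 1/T = 0.5 Hz` — no zero padding, the default
grid is exactly the window's natural resolution. Each window is mean
removed (linear detrending is unnecessary above the 1-Hz analysis floor
once the signal is notch filtered). Per time–frequency bin the full
stack of `m = N_E × K` per-(epoch, taper) power estimates is retained;
the spectrogram is their mean, and across white-noise replications the
variance of that mean shrinks by ≈ `N_E · K` relative to a single
taper. The group-level ensemble uses one long segment per animal
(target `N_E = 6` mice), so epochs are biologically independent units.
Tapers are combined by plain averaging; no adaptive eigenvalue
weighting. The stored grid is truncated to 0.5–150 Hz.

## Jackknife inference maps

For two spectrogram ensembles on a common grid the per-bin statistic is
Δ = mean log10 power(second) − mean log10 power(first). Log power is
variance-stabilizing for spectral estimates; an epsilon floor (1e-30)
guards exact zeros. Each ensemble mean's variance is estimated by
delete-one jackknife over its m independent (epoch, taper) estimates —
for a plain mean this equals the sample variance/m, but the resampling
form is kept because it generalizes and is self-documenting — and the
two variances add. The ratio t = Δ/SE is referred two-sided to a
Student t with `DOF = 2·N_E·K` (36 at defaults); the explicit DOF
implies a finite-sample reference rather than a normal one. Bins are
classified +1 (second ≫ first), −1 (second ≪ first) or 0, and band
summaries report the fraction of each type ("probability densities",
the pie-chart numbers).

Two caveats are inherited deliberately from the method being
implemented: overlapping time windows are autocorrelated, so time steps
are *not* treated as independent replicates — independence lives only
across epochs and tapers, each time step being tested from its own
m-deep stack — and no correction across the thousands of bins is
applied by default, because the maps and their band densities are
descriptive summaries, not confirmatory tests. A Benjamini–Hochberg
flag exists for users who want adjusted maps. Under a true null the
flagged fraction calibrates to α (0.05 ± Monte-Carlo error), which the
acceptance suite measures.

Comparison ordering: in a comparison labelled "A vs B" the first
ensemble is A and the second B, so for "D-1 vs PRE" a +1 bin means
PRE power significantly exceeds D-1 power. The default comparison plan
tests the first post-baseline session against baseline and against each
later session.

## Comodulograms

Pearson correlation of log10 power time courses (spectrogram columns at
dt resolution) for every frequency pair; log power because spectral
power is heavy-tailed, with a raw-power flag available. The matrix is
symmetric with unit diagonal; constant-power rows yield undefined (NaN)
cells rather than spurious values. Note that bins closer than the taper
bandwidth (2W = 2 Hz) share data and are intrinsically correlated — the
structure near the diagonal is methodological, not physiological, which
is why region summaries exclude diagonal cells and convergence checks
look beyond the 2-Hz band. Region summaries over band × band rectangles
report mean ± SD with a 95 % CI of `mean ± t(0.975, n−1)·SD` over
cells; strength labels follow the conventional |r| ranges 0–0.2 weak,
0.2–0.5 moderate, 0.5–1.0 high. The power time series come from
spectrogram columns rather than epoch-wise spectra — a dialect of the
classic power–power comodulation analysis chosen for integration with
the multitaper arm. Phase–amplitude coupling is out of scope.

## Pipeline and determinism

`run_cohort_analysis` composes all stages per group × session and
writes CSV/JSON/HDF5 outputs plus a manifest (configuration hash,
package and numpy versions, generator seed when known). Identical
inputs and configuration produce byte-identical CSV/JSON. A session
whose epochs are all rejected is skipped with a warning and recorded;
a missing baseline session fails fast.

## Problem sizes used by the test and acceptance suites

All suites generate their data at run time. Recovery suites use: 64
ten-second epochs for aperiodic exponents; 20-second six-epoch white
ensembles × 20 seeds (≈ 220k bins) for null calibration; 20 seeded
preset cohorts of 10 + 10 mice at 180 s (the FFT window) for effect
recovery; single 300-s signals for comodulation; and one full 300-s
preset cohort through every stage including the multitaper and
inference arms. These sizes were chosen as the smallest at which the
measured quantities' Monte-Carlo error is comfortably inside the
asserted tolerances.

## Known limitations

- The artifact screen is amplitude/flat-line only; it will not catch
  broadband muscle noise or slow drifts inside the MAD envelope.
- The jackknife map tests each bin marginally; spatially clustered
  false positives are expected under the null and no cluster statistics
  are provided.
- The aperiodic fit has no knee parameter and no explicit peak model;
  strongly peaked spectra bias the plain fit (use the robust mode or
  restrict the range).
- Comodulogram values within one taper bandwidth of the diagonal are
  structurally inflated and should not be interpreted.
- Generator determinism is guaranteed per platform/library build;
  cross-platform reproducibility holds to floating-point rounding.
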
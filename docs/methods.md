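# Methods

This note documents the models behind `otsforce`, the parameters that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic-data generator does and does not emulate.

## 1. Force–extension model and loading-rate conversion

A sensor on a stretched single-stranded DNA template experiences a force
ramp set by the stretching speed and the template's compliance:

    r(F) = v · (dx/dF)⁻¹.

`ForceExtensionModel` is an extensible freely-jointed chain,

    x(F) = N·l · [coth(u) − 1/u] · (1 + F/S),   u = F·b / kBT,

with contour per base `l` (0.56 nm), Kuhn length `b`, stretch modulus
`S` and `N` bases. The Langevin bracket switches to its series expansion
u/3 below u = 10⁻⁴, keeping the curve continuous with x(0) = 0. The
stiffness dF/dx is analytic; `loading_rate_at_force` raises if it is not
finite and positive (a flat force–extension region), and `speed = 0` is
allowed as the explicit zero-rate limit.

**Defaults are *effective*, not polymer-physics constants.** The
measured speed series (0.23 / 0.58 / 1.2 / 3.7 pN/s at 20–300 nm/s near
43–45 pN) implies a nearly force-independent effective stiffness of
~0.012 pN/nm over the probed range, much flatter than a bare ssDNA FJC,
whose entropic compliance scales like 1/F². A literal ssDNA
parameterization (S ≈ 800 pN, full-template contour) would spread the
same speeds over two orders of magnitude in rate and push the low-force
end far below the observed bracket. The defaults — b = 2.0 nm, S = 60 pN,
N = 6500 — are therefore calibrated to the observed speed→rate mapping;
the low stretch modulus lumps enthalpic template stretching with series
instrument compliance. With them, speeds 20–300 nm/s map 16–55 pN into
0.22–4.75 pN/s and reproduce the measured series to ~25%. Every
parameter is configuration, and only the derivative enters the analysis.

## 2. Pull simulation and rupture mechanisms

`simulate_pull` builds the ramp by inverting x(F) on a 4000-point force
grid between the 5 pN hybridization tension and a 70 pN ceiling, sampling
at 0.05 s; force is non-decreasing by construction. Two rupture
mechanisms are provided:

- `gaussian_threshold(mean, sd)`: the empirical description of a probe's
  force distribution; each probe draws its rupture force directly.
- `bell_evans(k0, x‡)`: rupture as first passage of the force-dependent
  hazard k(F) = k0·exp(F·x‡/kBT) along the *actual* simulated ramp. The
  integrated hazard is accumulated by trapezoid quadrature and inverted
  against a unit-exponential draw — exact for the discretized ramp, no
  closed form needed, and it reproduces the increase of mean rupture
  force with loading rate (~kBT/x‡ per e-fold of rate).

Draws beyond the simulated force range are flagged censored, never
dropped, so censoring bookkeeping always sums to the number of probes.

## 3. Kymograph rupture detection

`detect_rupture` fits every possible two-segment (high→low) step by
exact least squares (vectorized over all changepoints; an exhaustive
search, so it can be checked against a brute-force oracle) and accepts
the step only when the drop exceeds `threshold_fraction` (default 0.5)
of the pre-step median; constant traces are censored, not errors. The
changepoint is reported as the first post-step frame, which biases the
rupture time late by at most one kymograph frame; the simulated
calibration chain samples kymographs at 0.1 s so the corresponding force
bias (half a frame × loading rate ≈ 0.24 pN at 300 nm/s) is small
against the ~1 pN accuracy of interest. Rupture force is linear
interpolation of the force channel at the detected time. The Gaussian
force fit defaults to MLE on the raw forces (mean, SD) — bin-choice
invariant — with a histogram least-squares mode for parity with
histogram-based figures.

## 4. Imaging model

`render_movie` places each activation as a **pixel-integrated** 2-D
Gaussian (erf differences, pixel-center convention, frame time = index ×
interval), so a spot's integrated intensity equals `unit_intensity`
exactly before noise; overlapping events sum. Poisson shot noise is
applied to signal plus uniform background. Defaults (100 nm pixels,
PSF σ = 1.2 px, 1000 photons/spot, 100 photons/px background) are a
typical single-molecule TIRF regime, giving a peak-pixel SNR ≈ 11.

`detect_spots` band-passes with a difference of Gaussians (σ, 2σ), takes
local maxima above twice the robust (MAD) band-pass noise, measures
intensity as the background-subtracted aperture sum within 3σ (98.9% of
a Gaussian's mass; the median of the frame is the background, valid
because spots are sparse), keeps spots whose aperture sum exceeds
`min_snr` × the aperture-propagated background noise (default 5), and
refines position by positive-part centroid. On rendered movies at the
default SNR this yields ≥ 90% recall with ≤ 5% false discovery, ~0.1 px
localization, and ~5% intensity accuracy — adequate for counting and
onset timing, with no super-resolution claims.

Unit-intensity calibration takes the **mode** of the spot-intensity
distribution (Gaussian-KDE peak; half-width at 80% of the peak as the
uncertainty) rather than the mean, because multi-molecule spots
contaminate the upper tail. Molecule counts are the rounded ratio to the
unit, clamped at zero with a warning for negative inputs.

`delta_stack` forward-differences a channel and clamps negative
increments (the quantity is a signal *increase*; quenching steps are
handled separately), with an optional spatial median filter;
the unclamped differences telescope exactly to (last − first) frame.
Track linking is greedy nearest-neighbour under `max_disp` with gap
closing up to `max_gap` missed frames — sufficient for the
slowly-moving, well-separated spots this analysis concerns; trajectories
alive in the final frame are flagged open (right-censored). Trace
alignment shifts each pixel so its reference-channel maximum sits at lag
0 (earliest frame on ties, ties counted; flat references excluded and
counted) and reports mean ± SE per lag.

## 5. Exponential dwell times under stroboscopic observation

All dwell-time statistics reduce to one likelihood
(`otsforce.exponential`). For decay time τ and stride T:

- **Exact observation** (T = 0): the MLE is the closed form
  Σ(all durations) / n(uncensored) — the classic censored-exponential
  estimator, and the identity the oracle tests check.
- **Ceil quantization**: a duration reported as k·T means the true value
  lies in ((k−1)T, kT]; the likelihood term is
  e^{−(k−1)T/τ} − e^{−kT/τ}. This is the right model for track
  lifetimes, where a spot alive for any part of a stride is seen for the
  whole stride. It matters: at the subcluster condition (τ = 9 s,
  T = 10 s) the naive duration average is ~14.4 s, 60% high, while the
  interval MLE and the cumulative-count fit both recover ~9 s.
- **Onset differences**: a movie-derived delay D = t_B − t_A is the
  difference of two onsets each rounded *up* to the stride, so the true
  delay lies in (D − T, D + T) with a triangular kernel. The exact
  marginal is P(D=0) = 1 − (τ/T)(1−ρ) and
  P(D=jT) = (τ/T)·ρ^{j−1}(1−ρ)², ρ = e^{−T/τ}, j ≥ 1. Using the
  one-sided ceil interval here would bias τ low by ~T/2 (~25% for the
  monocyte presets, where τ ≈ 2 strides).

Right-censored entries (movie ended before the second onset; censoring
time = movie end − t_A) contribute survival terms in every mode. The MLE
is a Brent search in log τ (tolerance 10⁻¹⁰); probabilities are floored
at 10⁻³⁰⁰ before logs. Alternative fits provided for parity with
figure-style analyses: `histogram_lsq` (stride-binned A·e^{−t/τ}) and
`cumulative_lsq` (N(1−e^{−t/τ}) through the cumulative count, evaluated
at the observed quantized durations, where it is also unbiased).
Durations are rounded at 10⁻⁹ s before binning to absorb floating-point
jitter.

The 90% CI is a seeded percentile bootstrap (default 1000 resamples;
resampling pairs/tracks with their censoring flags). The point estimate
is always included in the reported interval. A bootstrap was chosen over
profile likelihood as assumption-light and exactly reproducible given a
seed; empirically its 90% intervals cover the generative rate in ~90% of
pipeline replicates.

Loading-rate conversion is the monotone transform r = ΔF/τ with the CI
limits inverted and reordered. ΔF defaults to the measured 13.2 pN
increment of the dp16/dp30 pair (preferred over the 14 pN difference of
nominal thresholds) and is overridable. The chance that two different
receptors sequentially activate the same sensor is
1 − (1 − labeled_fraction·p)ⁿ ≈ 6×10⁻⁶ per sensor per frame at the
default labeling (0.6%) and activation (≤0.1%) levels, so sequential
onsets at one spot are attributed to a single bond.

## 6. What the generator emulates, and what it does not

`simulate_activation_events` draws event positions uniformly over the
field (≥ 5 PSF σ from borders to avoid truncated-PSF bias, and with a
minimum pairwise separation, default 8 px, so diffraction-limited spots
stay resolvable — mirroring the restriction of the analysis to isolated
spots in the low-density regime). Channel-A onsets are uniform over the
movie; B follows after an exponential delay; delays are generated
continuously and only *observation* quantizes them, matching
stroboscopic acquisition (short exposures every stride; exposure-time
integration is ignored since events are rare within one exposure).

`n_events` (default 150) is the pooled per-condition number of analysed
events, matching the scale of the measured per-condition delay
histograms: at the physical sensor density (0.7 µm⁻²) and labeled
fraction (0.6%), a single field holds well under one labeled sensor, so
conditions are pooled over fields/cells exactly as in the experiment.
Movie durations (300 s epithelial, 75 s monocyte) keep right-censoring
under ~10% for every preset.

Not emulated: photobleaching and blinking (each channel steps on once
and stays on — sufficient for onset statistics, wrong for intensity
*decay* studies), stage drift, chromatic offset beyond a constant,
cell-shaped spatial inhomogeneity (masks are inputs), per-molecule
force-trajectory shape (the exponential delay law is the generative
assumption, taken from the observed single-exponential decay), and any
sensor chemistry or thermodynamics (temperature enters only through
calibration-table rows). Passing recovery tests therefore validates the
estimators under the stated statistical model, not the microscopy
against such nuisances.

## 7. Problem sizes and determinism

Every generator is bit-reproducible from (preset, seed); the pipeline
derives its sub-seeds (events, rendering, bootstrap) from one integer.
Recovery tests use the preset defaults (150 events, 192 px field);
the CI-coverage suite uses 40 replicates per preset at a reduced size
(128 px, 80 events, 300 bootstrap resamples), which leaves the coverage
property unchanged while keeping the suite fast. The worked numbers in
the README are the scripts' actual output at seed 1.

## 8. Known limitations

- The effective force–extension defaults are a calibration, not a
  measurement; they should be refit if the conversion is applied to a
  different template or instrument.
- Greedy nearest-neighbour linking and pairing are deterministic and
  auditable but not globally optimal; at high spot densities a
  assignment-problem linker would be preferable.
- The percentile bootstrap can slightly undercover for small numbers of
  pairs (≲ 30); the pipeline enforces ≥ 20 uncensored pairs.
- The calibration table stores the 44.0 ± 3.9 pN value for the 18 bp
  GC-61% probe at 100 nm/s (its speed-series entry, 43.8 pN, is the same
  measurement rounded differently; table keys are unique).
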
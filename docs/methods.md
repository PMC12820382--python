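# Methods

## Fibril populations and the area-loss rule

Fibril diameters d (nm) are treated as draws from a two-component Gaussian
mixture; cross-sectional area assumes a circular cross-section,
CSA = πd²/4. The built-in reference mixture uses the printed subpopulation
statistics of a 416-fibril bovine extensor dataset (S1: 75.9 ± 21.1 nm,
n = 148; S2: 165.9 ± 26.7 nm, n = 268; full population 133.9 ± 49.7 nm). By
default sampling is *stratified* — exactly 148 and 268 draws per component —
mirroring a dataset with fixed subpopulation head counts; multinomial
weights are available. Draws below a 10-nm floor are redrawn from their
component: the Gaussian left tail would otherwise produce non-physical
diameters, and no published cleaning rule exists for the original data, so
the floor is an explicit, configurable artifact parameter.

Degradation is driven by the linear per-5-h area loss
ΔCSA = −65.94 + 0.0721·CSA_i (nm² per 5 h), whose constants come from a
prior AFM calibration and are not re-fit here. The rule has a fixed point at
CSA = 65.94/0.0721 ≈ 914.56 nm² (d ≈ 34.1 nm); below it the raw rule
predicts growth, which is non-physical for a degradation process, so losses
are clamped to ≥ 0 by default (a flag disables the clamp for fidelity
experiments). The subpopulation and size-independent models average the
*unclamped* individual ΔCSAs at t = 0 — so all three models remove the same
total area in the first step when nothing clamps or depletes — and clamp
only at application time. Fibrils driven to CSA ≤ 0 are floored at zero,
flagged with their depletion time, excluded from diameter-distribution
outputs, and counted at their full initial diameter in mean-decrease
summaries. A 24-h snapshot is defined only through the interpolation
csa₂₄ = csa₂₀ − (4/5)(csa₂₀ − csa₂₅).

The S1/S2 split is 1-D k-means with k = 2 (10 restarts, fixed seed, labels
ordered so S1 has the smaller mean). For 1-D data the optimal
within-cluster-sum-of-squares 2-partition is a contiguous threshold split,
which the tests verify against exhaustive search on small instances.

## Power analysis

The minimum detectable effect for a one-sided two-sample t-test with equal
group sizes n and common SD s solves
P(T > t₁₋α,df | ncp = Δ/(s·√(2/n))) = power. The default solver uses the
noncentral-t with per-group degrees of freedom df = n − 1, a conservative
choice that reproduces the published planning table at its printed 1-decimal
precision for all six (population × power) cells; the lighter normal
approximation Δ = (z₁₋α + z_power)·s·√(2/n) (within ~0.2% at these n) is
available via `method="normal"`. α defaults to 0.05 one-sided. Required
incubation time interpolates the cumulative mean-decrease curve linearly
between 5-h grid points and takes the ceiling in whole hours; subpopulation
hours use the subpopulation's own curve (its fibrils degraded within the
full-population run, then averaged within the cluster).

Note a structural sensitivity: for the full reference population the 95%
crossing lands almost exactly on the 13-h boundary, so over independently
sampled synthetic populations the whole-hour answer alternates between 13
and 14; downstream summaries therefore average over ≥ 5 seeds.

## Synthetic SEM images

The generator renders each fibril as a smooth tube along a polyline
centerline: a flat-top radial profile with an error-function edge ramp
(σ = 1 px, ≈ 2 px transition), axial sinusoidal intensity modulation at the
D-band period, composited over a uniform background by pointwise maximum,
with optional additive Gaussian noise, clipped to the 8-bit range. The edge
ramp makes both the half-contrast width and the steepest-gradient width
equal the nominal diameter, so "edge" is well defined for the detector.
Default calibration is 4 nm/px (the true SEM pixel calibration is
unpublished); at that scale a 250-nm piece is ≈ 62 px and the 36–70 nm band
window sits well below Nyquist. Truth tables carry per-fibril mean diameter,
chord orientation, curvature on the 250-nm piece grid, band period, and arc
length.

What the generator does *not* emulate: fibril overlap and crossing,
detector/charging physics, coating grain, gap/overlap step banding (a pure
sinusoid is used, since only a dominant period is estimated), or 3-D
perspective. Passing the pipeline-vs-truth tests therefore demonstrates
correctness of the measurement geometry and spectral estimation, not
robustness to every real-image artifact.

## Piecewise measurement

Traces (≥ 2 µm of arc, else rejected) are resampled to equal-arc-length
250-nm pieces; the trailing remainder is discarded to keep piece statistics
homogeneous. Per piece, five perpendicular profiles at fractions
{0.1, 0.3, 0.5, 0.7, 0.9} of the piece are sampled by bilinear
interpolation at 0.5-px steps out to ±200 nm, smoothed with a 3-px moving
average; the diameter is the mean distance between the steepest rising
gradient on one side of the centerline and the steepest falling gradient on
the other (steepest-gradient rather than half-maximum: robust to the edge
ramp and to SEM edge brightening, and invariant to intensity rescaling).
Pieces whose profiles exit the frame are excluded. Orientations live on the
half-turn (−90°, 90°]; fibril means use the doubled-angle axial mean;
curvature is Σ|Δθ| over successive pieces divided by the arc length spanned
between the first and last measured piece (piece-index aware, so excluded
pieces do not shrink the span). Alignment subtracts the image's axial mean
orientation from each fibril, making the dispersion invariant under global
scene rotation.

## D-band estimation

The axial profile averages intensities at perpendicular offsets
{−2…+2} px along the full traced length at 1-px arc steps. Detrending
subtracts a moving-average baseline (default window 210 nm ≈ 3× the upper
band bound — long enough to pass the D-band nearly untouched while removing
drift); the zero-mean profile is linearly interpolated onto 2^k + 1 points
(2^k the smallest power of two ≥ the sample count). The one-sided FFT power
spectrum is normalized so total power equals the sum of squared samples
(Parseval), no taper by default (a Hann option exists). The period is the
inverse of the maximum-power frequency restricted to periods in [36, 70] nm,
ties broken toward the longer period; the SNR annotation is peak over median
in-window power. Because single-fibril spectra are noisy, per-sample spectra
are averaged pointwise before the peak pick — the tests demonstrate cases
where individual spectra mis-peak while the average does not. Resolution is
one frequency bin: for a 2.5-µm fibril at 4 nm/px, ≈ 0.7 nm of period at
52.6 nm; no sub-bin interpolation is attempted.

## Problem sizes and determinism

Simulation-backed quantities use populations of n = 416 (matching the
reference head count) averaged over 10 seeds, 1000-fibril populations for
clustering characterization, and ≥ 10 rendered fibrils for the averaged
D-band estimate; these sizes hold sampling error well inside the comparison
tolerances while keeping runs desk-scale. Every stochastic step — mixture
sampling, k-means restarts, image noise — consumes an explicit seed, and
fixed-seed runs are bit-identical.

## Known limitations

* The degradation models are phenomenological area-removal rules; no enzyme
  kinetics, no refit of the ΔCSA constants.
* Depletion handling (floor at zero, full-diameter contribution to mean
  decrease) is an artifact decision; the original analysis's choice is not
  documented.
* The measurement pipeline assumes non-overlapping fibrils with both edges
  visible; traces are inputs, not computed segmentations.
* k-means with k = 2 is assumed appropriate; no model selection over the
  number of subpopulations.
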
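# Methods

This note documents the models, conventions and design choices behind
`nirsfuse`, in the order the pipeline runs them, together with what the
synthetic benchmark does and does not demonstrate.

## Montage and channels

A montage is a list of source/detector optodes with 3-D scalp positions in
millimetres. The packaged default is the left-motor 10-20 layout (sources
FC3, C3, CP3; detectors FC5, C5, CP5, FC1, C1, CP1) using standard scalp
coordinates tabulated in `data/montage_1020.csv`. Channels are all
source×detector pairs in a fixed order — sources outer, detectors inner,
both in montage order — and every downstream channel index (`ch00`…)
refers to that order. Under these coordinates the four pairs FC3-CP5,
FC3-CP1, CP3-FC5 and CP3-FC1 exceed 60 mm and are excluded by the default
distance filter, leaving 14 of 18 channels; the tests pin this exclusion
set. Channel distances feed the Beer-Lambert system directly.

## Modified Beer-Lambert conversion

Intensities are referenced to the mean over a baseline window (default
0-10 s), giving differential optical density `ΔOD = −log10(I/I₀)`; the
scattering offset G(λ) cancels in the difference and is never estimated.
Per channel, the 2×2 system over wavelengths (760, 850 nm) is solved for
(ΔHbO, ΔHbR). Units are closed as: ε in 1/(mM·mm) (packaged standard
values, overridable), distance in mm, DPF dimensionless (default 6.0 at
both wavelengths, a common adult value), concentrations reported in µM.
The system is refused when its condition number exceeds 1e8. Only the two
hemoglobin chromophores are modelled; other absorbers (water, lipids) are
outside scope, as is any absolute (non-differential) concentration
estimate.

Note one deliberate nuance: because I₀ is the *arithmetic* mean intensity,
the ΔOD over the baseline window is zero-mean only to first order; the
exact identity is that the mean of `10^(−ΔOD)` over the window is 1. The
tests assert the exact form.

## ICA cleaning

FastICA (symmetric fixed-point, logcosh contrast, eigendecomposition
whitening) is implemented natively and fitted per hemoglobin stream on the
continuous channel-by-sample data *before* epoching. Determinism comes
from seeding the initial unmixing matrix; non-convergence raises (or, in
the pipeline wrapper, returns the data unchanged with a warning, since an
unconverged filter would inject structure rather than remove it).
Component rejection is heuristic and pluggable; the default flags
components with excess kurtosis above 5.0, which captures spike and step
artifacts while sparing oscillatory physiology (a pure sinusoid has excess
kurtosis −1.5). Alternative algorithms (Picard, extended Infomax) can be
registered behind the same model contract; no claim is made about their
relative separation quality, since no quantitative criterion for such a
comparison is established here.

## Classical features

The four time-domain moments use deliberately preserved mixed
normalizations: variance with 1/N; skewness and kurtosis with a 1/N
numerator over a 1/(N−1) inner variance, kurtosis as excess. These differ
from the textbook g1/g2 at small N and the difference vanishes as N grows;
they are kept exactly as specified for the method being implemented (the
Hjorth activity below uses 1/(N−1) — both conventions live in their
respective homes on purpose). Epochs shorter than 4 samples or with zero
variance are errors naming the epoch/channel.

PSD is an averaged modified periodogram: Hann window, 50% overlap, segment
`min(N, 256)`, mean-removal detrend. Three frequency features are exposed
rather than one — peak frequency (ties to the lowest frequency), peak
power, and the mean power over the FWHM band (the contiguous bins around
the peak with power ≥ half the peak, at bin resolution, no interpolation) —
because the single "maximum frequency of the highest average power in the
FWHM band" is ambiguous as a scalar.

## Fused feature generation

Per channel of the continuous cleaned stream: Hjorth activity
`α = var(x)` (N−1); mobility `β = var(fs·diff(x))/α`, the plain ratio
without the conventional square root (`hjorth.sqrt_mobility` restores the
standard definition); a 5-level decimated `db4` decomposition with
periodized boundaries; within each detail array the `floor(0.25·len)`
largest-|value| coefficients are zeroed ("extreme" coefficients as
artifacts — `trim_tail` also offers `smallest` and `both`, since removing
the low-magnitude tail is an equally defensible reading of coefficient
denoising); the channel weight `w` is the mean *absolute* surviving
level-4 detail coefficient (a signed mean of detail coefficients is ≈ 0 by
construction and would annihilate the weighting). Then
`fnew = (w + α + β)·f` and `fnew1 = w·(h + s)` with `h` the Hilbert
envelope (or instantaneous phase by config) and `s` a single-level
undecimated symlet (`sym4`) approximation computed by circular convolution
with the scaling filter at unit DC gain. Constant channels (zero activity)
yield all-zero fused rows with a warning instead of aborting.

**Selectivity caveat.** The fusion gain `w + α + β` is dimensionally
inhomogeneous, and its three terms are not equally activity-selective. The
activity term genuinely amplifies responding channels (their variance is
higher), and on the synthetic benchmark the activity-weighted series
amplifies active over inactive channels by well over 2×. The mobility
ratio, however, behaves as `β ≈ var(fs·diff)/α`: its numerator is
dominated by broadband measurement noise and is nearly channel-independent,
so β is *largest on low-variance (inactive) channels* and, at 12.5 Hz,
numerically dominates w and α expressed in µM². The full printed gain
therefore does not amplify active channels on broadband-noise data; the
discriminative value of the fused set comes from the per-channel gain
pattern itself (monotone per-channel scalings are irrelevant to tree
learners and are standardized away for KNN/LDA), not from absolute
amplification. The property tests assert the selective part; the
classification benchmark measures the end effect.

Fused per-epoch features are mean, variance and energy (mean square) of
`fnew` and `fnew1` per channel — 84 features for 14 channels — with
stable, unique column names.

## Classification

Two independent binary detectors: MD (label 2) vs. rest-and-SN, SN (label
3) vs. rest-and-MD. Each runs per stream (HbO, HbR) and per feature set
(classical, fused). Cross-validation is stratified k-fold (default k = 5 —
the fold count is otherwise unspecified in the source method), shuffled
with a derived seed; reported accuracy is the fold average (per-fold
confusion matrices are retained). KNN (k = 10, Euclidean, uniform votes;
vote ties resolve toward the negative class, distance ties toward earlier
training rows) and LDA consume features standardized on the training fold;
tree ensembles consume raw features. The boosted learners interpret the
source method's "50 epochs with a batch size of 64" as 50 boosting rounds;
batch size has no meaning for trees (or for KNN/LDA) and is ignored.
LightGBM's `min_child_samples` is lowered to 5 because fNIRS feature
tables have tens, not thousands, of rows.

## Rank tests

Mann-Whitney U reports U₁ of the first sample, with full-enumeration exact
p-values when n₁+n₂ ≤ 12 and the data are tie-free, else the normal
approximation with midranks, tie correction and continuity correction.
Kruskal-Wallis H uses the chi-square approximation with the tie-correction
divisor; a fully degenerate pooled sample returns H = 0, p = 1 so constant
features report "no separation" rather than erroring. Both default to
two-sided distribution-equality hypotheses at α = 0.05. The separability
report runs H across the three classes and U for motor (labels 2∪3)
vs. rest per feature; aggregation across features is left to the user
because no canonical vectorization exists. The suite verifies type-I
calibration (rejection rate within [0.035, 0.065] under the null at
α = 0.05, n = 30 per group, 2000 replicates).

## Synthetic session generator

The generator emulates the acquisition conditions the pipeline targets —
14 retained channels at 12.5 Hz, three trial classes (rest / MD / SN),
20 trials per class of 10 s with 10 s inter-trial intervals and a 15 s
lead-in — and emits raw *intensities* through the forward Beer-Lambert
model (I₀ = 1), so no stage is bypassed. Event-locked ΔHbO is a boxcar
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
ratio 1/6, unit plateau normalization); MD drives channels {3,4,5} and SN
{9,10,11} (0-based) at 1.0 µM; ΔHbR = −0.3·ΔHbO, the typical
anticorrelated attenuated response, which is what makes the HbO ≥ HbR
accuracy ordering reproducible. Nuisance terms per channel: cardiac
1.1 Hz (0.3 µM), respiratory 0.25 Hz (0.3 µM), Mayer waves 0.1 Hz
(0.2 µM) with seeded random phases, white noise (σ = 0.2 µM),
exponentially decaying motion spikes (0.5/min, ±5 µM) and rare baseline
steps (2% of trials, ±1 µM), all logged in the ground truth. A single
seed drives one named generator; identical (config, seed) reproduces the
session bit for bit.

What the generator does *not* emulate: serial correlation of the noise
beyond the three sinusoids, systemic physiology shared across channels
(each channel's oscillation phases are independent), optode drift, skin
blood-flow responses, subject-level variability, or overlapping
hemodynamic responses (the cadence is fixed). One consequence of the
fixed 20 s cadence is that all three nuisance periods divide it exactly,
so the oscillations are trial-locked; block averages do not suppress
them, but the standard task-minus-rest contrast cancels them, which is
how ground-truth recovery is scored (correlation ≥ 0.8 in active
channels). Passing the benchmark therefore shows the pipeline's stages
compose correctly and are sensitive at a realistic contrast-to-noise
ratio; it does not certify performance on real recordings, where the
unmodelled structure above dominates the difficulty.

## Problem sizes and determinism

The default benchmark is one 1215 s session (15 188 samples × 14
channels × 2 wavelengths), 60 trials, 5-fold CV — a few seconds end to
end, so tests and the acceptance script run comfortably on one CPU.
Every stochastic stage (schedule shuffling, noise, ICA initialisation,
fold assignment, learner seeds) derives its own sub-seed from the global
seed by hashing the stage name, keeping stages independently reproducible.
Numerical tolerances: Beer-Lambert round trip 1e-10 µM; wavelet perfect
reconstruction 1e-10; whitening covariance 1e-8; ICA convergence tol 1e-6
(max 1000 iterations); LDA uses the SVD solver, which tolerates singular
pooled covariance without an explicit ridge.

## Known limitations

- No bandpass filtering stage: cleaning is ICA-only, so narrowband
  physiological oscillations that are not spike-like survive into the
  features. Real-data use would normally add a 0.01-0.2 Hz bandpass before
  feature extraction.
- The 25%-trimming tail direction is genuinely ambiguous in the source
  method (both "remove the extreme artifacts" and "remove the
  low-magnitude noise" readings exist); both are implemented, `largest` is
  the default, and conclusions that depend on the choice should sweep it.
- Whether the symlet/Hilbert streams should be computed from the raw
  channels or from `fnew` is unspecified; the literal reading (raw
  channels `fᵢ`) is implemented.
- Mann-Whitney/Kruskal-Wallis statistics depend on which features are fed
  in; no canonical aggregation is provided, so reported statistics are
  per-feature.
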
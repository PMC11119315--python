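# nirsfuse

Decoding covert motor activity from functional near-infrared spectroscopy
(fNIRS) recordings. The package targets the two-task motor-imagery paradigm
used in optical brain-computer interfaces: detecting **mental drawing (MD)**
and **spatial navigation (SN)** epochs against rest, from a 14-channel
left-motor-cortex montage sampled at 12.5 Hz with 760/850 nm light.

It is written for BCI and neuroimaging researchers who want a transparent,
fully seeded reference pipeline: every stage from raw two-wavelength
intensities to cross-validated task accuracies is reproducible from a single
integer seed, and a synthetic session generator with known ground truth
exercises the whole chain end to end.

## The method

1. **Optics to hemodynamics.** Raw intensities are referenced to a baseline
   window and converted to differential optical density,
   `ΔOD(t, λ) = −log10 I(t, λ)/I₀(λ)`. The modified Beer-Lambert law

   `ΔOD(t, λ) = Σᵢ εᵢ(λ) Δcᵢ(t) · DPF(λ) · d`,  i ∈ {HbO, HbR}

   is solved per channel and sample as a 2×2 linear system for the
   oxygenated/deoxygenated hemoglobin changes ΔHbO, ΔHbR (µM), with ε the
   molar extinction coefficients, `d` the source-detector distance (mm) and
   `DPF` the differential pathlength factor. Differential referencing
   cancels the unknown scattering offset G(λ).
2. **ICA cleaning.** The channel data are modelled as `x = A s` with
   statistically independent non-Gaussian sources; a natively implemented
   symmetric fixed-point FastICA estimates the unmixing matrix `W`,
   high-kurtosis (spike-like) components are zeroed, and the remainder is
   back-projected.
3. **Classical features.** Per epoch and channel: mean, variance, skewness,
   excess kurtosis (exact printed normalizations), plus Welch-PSD peak
   frequency, peak power, and FWHM-band mean power.
4. **Fused features.** Per channel i: Hjorth activity `αᵢ = var(fᵢ)` and
   mobility `βᵢ = var(dfᵢ/dt)/αᵢ`; a 5-level Daubechies decomposition whose
   extreme 25% of detail coefficients are removed; the channel weight `wᵢ` =
   mean |surviving level-4 coefficient|. Two fused series are built:

   `fnewᵢ(t) = (wᵢ + αᵢ + βᵢ) · fᵢ(t)` and `fnew1ᵢ(t) = wᵢ · (hᵢ(t) + sᵢ(t))`

   with `hᵢ` the Hilbert amplitude envelope and `sᵢ` an undecimated symlet
   approximation. Per-epoch mean/variance/energy summaries of both series
   form the fused feature set.
5. **Decoding.** Two *independent* one-vs-rest binary classifiers — MD
   vs. rest, SN vs. rest — run separately on the HbO and HbR streams and on
   classical vs. fused features, with seeded stratified k-fold
   cross-validation. Learners: KNN (k = 10, Euclidean, uniform), LDA, and
   LightGBM / XGBoost gradient boosting (50 rounds).
6. **Validation.** Mann-Whitney U (motor vs. rest) and Kruskal-Wallis H
   (three classes) rank tests check fused-feature separability at α = 0.05.

## Worked example

```python
from nirsfuse.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_dict({"seed": 7, "learner": {"kinds": ["gbm_light", "knn"]}})
report = run_pipeline(cfg)
for key in sorted(report.summary):
    print(f"{key:35s} {report.summary[key]:.3f}")
```

prints (task | stream | feature set | learner → mean CV accuracy over 60
synthetic trials, 20 per class):

```
MD|HbO|classical|gbm_light          0.983
MD|HbO|classical|knn                1.000
MD|HbO|fused|gbm_light              1.000
MD|HbO|fused|knn                    1.000
MD|HbR|classical|gbm_light          0.967
MD|HbR|classical|knn                0.967
MD|HbR|fused|gbm_light              0.967
MD|HbR|fused|knn                    0.917
SN|HbO|classical|gbm_light          1.000
SN|HbO|classical|knn                0.983
SN|HbO|fused|gbm_light              1.000
SN|HbO|fused|knn                    0.983
SN|HbR|classical|gbm_light          0.950
SN|HbR|classical|knn                0.883
SN|HbR|fused|gbm_light              0.950
SN|HbR|fused|knn                    0.950
```

The qualitative structure is the point: fused features match or beat the
classical set, and the HbO stream (which carries the full-amplitude
response) beats the attenuated, anticorrelated HbR stream. With the default
generator both tasks are decoded essentially perfectly from HbO; the HbR
stream is harder by construction.

The same run is available from the shell:

```bash
nirsfuse run --seed 7 --out results/
nirsfuse simulate --seed 7 --out session/        # write a raw session to disk
nirsfuse features --data session/raw.csv --montage session/montage.csv \
    --events session/events.csv --out features/
```

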
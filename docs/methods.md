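# Methods

This note records the scientific and numerical choices behind `ecglite`:
what each stage computes, which knobs matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Signal model and preprocessing

The pipeline assumes a single-lead ECG sampled at 128 Hz. Records at other
rates (e.g. 360 Hz Holter exports) are polyphase-resampled to 128 Hz before
anything else, with annotation indices rescaled by the rate ratio and
rounded to the nearest sample; resampling is the preprocessing module's
job so that readers stay lossless.

**Baseline wander removal.** A 4th-order Butterworth high-pass at 0.5 Hz
(SOS form) removes respiration/motion drift. It is applied
forward–backward (`sosfiltfilt`) by default: the pipeline is offline, and
zero-phase filtering avoids distorting QRS morphology; the effective
magnitude response is then the squared one-pass response. Single-pass
causal filtering is available via `zero_phase=False`. Signals must exceed
the filter's padding length (24 samples at order 4).

**Wavelet denoising.** Each 1000-sample window is decomposed with sym4 to
the maximum level its length admits — `floor(log2(N/(support−1)))`, which
is 7 for N = 1000 and the 8-tap sym4 filters. In every detail band the
threshold is 0.04 × that band's largest absolute coefficient, and
coefficients below it are zeroed (hard thresholding; approximation
coefficients are untouched). Hard thresholding is the plain reading of
"filtering out" small coefficients; soft shrinkage is available behind
`soft_threshold=True`. With threshold factor 0 the transform round-trips
to within 1e-8 (perfect reconstruction), which the tests assert for a
range of window lengths.

**Normalization.** z-scoring is per window with the population standard
deviation; a constant window maps to zeros rather than NaNs. Per-window
(not per-record) scoring is the only choice that guarantees scale
invariance across devices *after* windowing.

**Segmentation and labeling.** Windows are consecutive, non-overlapping,
exactly 1000 samples, starting at sample 0; a short trailing remainder is
dropped and any window whose span contains a noise annotation is excluded.
Beat-level (Holter) windows take the majority symbol among the beats they
contain, rejecting windows with no beats or with symbols outside
{N, L, R, A, V}; ties break toward the non-N symbol, then by the fixed
order L < R < A < V (the deterministic tie-break is a package choice — any
rule works, but it must be stated). Rhythm-level (smartwatch segment
table) windows inherit their segment's class code; codes 1.0/2.0/3.0
collapse to Arrhythmia and 0.0 to Normal for the binary task. One-hot
orders are fixed: (N, L, R, A, V) and (Normal, Arrhythmia).

## Architectures and accounting

The two reference specs are declarative layer lists; shape propagation,
parameter counting and FLOP estimation are pure arithmetic on the spec,
and the training backend realizes the same spec, so the two code paths
cross-check each other (the tests assert exact parameter equality for both
references and both ablation variants).

The multiclass pooling schedule (pool 2: stride 1 first, stride 2 after)
is the unique simple schedule consistent with the length chain
1000→999→499→249→124 and the 15,872 = 124×128 flatten; the binary
schedule (pool 3, stride 2 throughout) likewise uniquely reproduces
499/249/124/61 and 7,808 = 61×128. Both conv stacks use kernels
(11, 13, 15, 17) with filters (16, 32, 64, 128). Dropout defaults to 0.5
(a conventional value; the rate is configurable and was not tuned).
Softmax is modeled as an explicit terminal layer.

FLOPs are reported under one documented convention — 2 × MACs, counting
conv as out_len·k·C_in·C_out and dense as in·out, ignoring biases, pooling
and activations — giving 58,830,080 for the binary spec. Published FLOP
figures for the same network vary by counting tool and convention; this
module states its convention rather than matching any particular counter.

## Training backend

No GPU framework is assumed: the backend is a compact numpy
implementation — im2col convolutions, max-pool with argmax scatter,
inverted dropout, Glorot-uniform initialization, Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-7) on categorical cross-entropy with the
usual fused softmax gradient. Every stochastic element (init, shuffling,
dropout, resampling) draws from generators seeded by the run seed, so two
runs with the same seed and data are bit-identical. Gradients are verified
against central finite differences (max error ~1e-10 in float64).
Arithmetic defaults to float32 for speed on CPU; float64 is available
(`dtype=`) and is used by the gradient-check test. Probabilities are
renormalized in float64 on output.

Training defaults follow the protocol the reference networks were designed
under: 50 epochs, batch 32, Adam at learning rate 0.001 (recorded in
`TrainConfig`; the learning rate is the optimizer's conventional default,
stated explicitly since it matters for reproduction).

## Evaluation protocol

Splits operate on patients. Grouped holdout puts ⌈0.8·P⌉ shuffled patients
in training; LOSO makes P folds, each testing exactly one patient. LOSO
metrics are computed on predictions *pooled* across folds — one global
confusion matrix — not averaged per fold, since per-fold metrics on a
single patient are often degenerate (one class present). Class balancing
oversamples minority classes with replacement up to the majority count and
is applied to training folds only; resampling test data would bias the
estimate.

Metrics: per-class one-vs-rest sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/total; global accuracy = trace/total;
global sensitivity/specificity are macro averages. For K = 2 the
sens(class₀) = spec(class₁) duality holds identically and is asserted as a
property. F1 and AUROC take Arrhythmia as the positive class in the binary
task and macro-average one-vs-rest otherwise (the averaging convention is
a package choice). AUROC is the rank statistic
P(score⁺ > score⁻) + ½P(tie), computed with midranks; it agrees with an
exhaustive pairwise oracle on all small inputs and with scikit-learn on
random data. Bootstrap CIs resample test windows with replacement
(B = 1000 by default), recompute the metric, and report the 2.5th/97.5th
percentiles; resamples that lose a class are redrawn and counted.

## Synthetic cohorts

The generator exists so that every stage — including end-to-end LOSO
training — is exercised without restricted or downloaded data. Each beat
is a sum of five Gaussian bumps (P, Q, R, S, T) with per-class morphology:
NSR has low RR variability (CV 0.03) and a full PQRST; AF has high RR
variability (CV 0.25), no P waves and a faster mean rate (95 vs 70 bpm);
PAC/PVC are sinus rhythm with premature beats (coupling interval
0.55–0.70 of the mean RR, followed by a compensatory pause), narrow with a
reduced early P for PACs and wide (QRS widths ×2.5), P-free, with
discordant T for PVCs. A 0.25 Hz sinusoid (0.15 mV) emulates respiratory
baseline wander and white noise (0.04 mV) the wideband floor. These
defaults were chosen once as plausible desk-scale values for the regime
the pipeline targets and produce a clearly separable NSR/AF contrast;
amplitudes are quantized to the 200 adu/mV ADC grid so that WFDB
round-trips are exact. R-peak annotations are emitted by construction.

What the generator does **not** emulate: realistic noise taxonomies
(electrode motion, muscle artifact), PQRST shape variability within a
patient, fibrillatory f-waves, conduction-block morphologies (L/R classes
are never generated), or any device-specific artifact. Passing end-to-end
tests therefore demonstrates that the pipeline's machinery is correct and
that the protocol detects a separable rhythm difference — not that the
models reach any particular performance on real smartwatch or Holter data.

## Grad-CAM

Standard 1D Grad-CAM: channel weights are temporal means of ∂(class
logit)/∂A at a conv layer (last conv by default), the weighted activation
sum passes through ReLU, is linearly interpolated to the input length and
normalized by its maximum (identically-zero maps are flagged rather than
divided). The saliency-localization test scores maps from the *first* conv
layer, whose temporal grid is finest; at the last conv layer one output
step spans ~16 input samples and maps over windows mixing normal and
ectopic beats smear across beat boundaries.

## Scaled-down study sizes

End-to-end tests run deliberately small: 8-patient cohorts, 120 s records
(12 windows/patient), 8–15 epochs. These sizes were fixed after a single
calibration run of each experiment and are the package's desk-scale
defaults for its own test suite; the `TrainConfig` defaults (50 epochs)
remain the full protocol. The separable-cohort LOSO run reaches 97.9%
pooled accuracy; the imbalanced-cohort comparison (6 NSR/2 AF patients,
noise 0.08 mV, 8 epochs) shows minority-class sensitivity rising from 0%
to ~54% when training folds are rebalanced.

## Known limitations

- The WFDB reader covers single-channel format-16 records with
  byte-pair/SKIP annotations — the `mitdb` subset of the format — not
  multi-channel, format-212, or auxiliary-field-rich files.
- The backend trains on CPU in memory; it is adequate for the reference
  networks at cohort scale but is not a general deep-learning framework
  (no checkpointing mid-epoch, no schedulers, no GPU).
- AUROC on pooled LOSO predictions mixes per-fold score calibrations;
  this follows the pooled-metrics protocol but can differ from per-fold
  averaging.
- Binary labels are rhythm-level and flow through segment tables; the
  continuous-record path labels windows from beat symbols only.
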
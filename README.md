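# ecglite

Lightweight 1D-CNN arrhythmia detection for single-lead ECG, built for the
smartwatch regime: short 128 Hz recordings, modest compute budgets, and
evaluation that must generalize to *new patients*, not new windows.

The package implements the full pipeline as a library plus a thin CLI:

1. **I/O** — WFDB-style continuous records (`.hea`/`.dat`/`.atr`, the
   PhysioNet `mitdb` layout) with beat annotations N/L/R/A/V and noise
   markers, and pre-segmented 30-s tables with class codes
   0.0 = NSR, 1.0 = AF, 2.0 = PAC, 3.0 = PVC.
2. **Preprocessing** — 0.5 Hz 4th-order Butterworth high-pass (baseline
   wander removal), per-window sym4 wavelet denoising with level-wise hard
   thresholds τ_j = 0.04 · max|d_j|, per-window z-scoring, non-overlapping
   1000-sample windows (≈ 7.81 s at 128 Hz) with noise-marked windows
   dropped, and one-hot class coding (5-class beat labels or binary
   Normal/Arrhythmia).
3. **Architectures** — two declarative 1D-CNN reference specs with analytic
   shape propagation, exact trainable-parameter counts and a documented
   2×MAC FLOP estimate, plus ablation variants (three conv layers; all
   kernels +2).
4. **Training & evaluation** — patient-wise grouped 80/20 holdout and
   leave-one-subject-out (LOSO) cross-validation, optional minority-class
   oversampling on training folds, and the full metric suite: per-class and
   global accuracy/sensitivity/specificity, F1, rank-statistic AUROC, and
   95% bootstrap CIs. A small numpy training backend (Adam, categorical
   cross-entropy, seeded and deterministic) realizes the specs.
5. **Explanations** — 1D Grad-CAM saliency maps over input windows.
6. **Synthetic cohorts** — a seeded generator of class-dependent ECG
   (regular NSR, irregular-RR P-free AF, early narrow PACs, wide PVCs) with
   baseline wander and noise, so the entire pipeline runs and is tested
   without any data download.

## The two reference networks

Both take a z-scored 1000-sample window and stack four same-padded Conv1D
layers (filters 16/32/64/128, kernels 11/13/15/17, ReLU), each followed by
a valid max-pool:

| spec | pooling | length chain | flatten | head | params |
|---|---|---|---|---|---|
| `mitbih_multiclass` | size 2; stride 1 then 2,2,2 | 1000→999→499→249→124 | 15,872 | dense 35 → 5 | 732,791 |
| `simband_binary` | size 3, stride 2 | 1000→499→249→124→61 | 7,808 | dense 128 → 2 | 1,176,866 |

The binary model's 1,176,866 trainable parameters round to 1.2 M; its FLOP
estimate under the 2×MAC convention (conv: out_len·k·C_in·C_out, dense:
in·out, biases/pooling/activations ignored) is 58,830,080.

## Worked example

Generate an 8-patient NSR/AF cohort, preprocess the 30-s segment table into
binary-labeled windows, and run LOSO with the binary reference model:

```bash
ecglite describe --spec simband_binary
ecglite simulate --patients 8 --mix NSR=0.5,AF=0.5 --duration 120 \
    --seed 7 --segments-csv --out cohort
ecglite preprocess --segments cohort/segments.csv --mode binary --out windows.npz
ecglite train --windows windows.npz --spec simband_binary --mode loso \
    --epochs 15 --seed 0 --out run
```

`describe` prints the layer-by-layer shape trace ending in
`flatten size: 7,808`, `trainable parameters: 1,176,866` and
`FLOPs (2 x MAC convention): 58,830,080`. The `train` command prints the
pooled LOSO metrics; on this cohort and seed:

```json
{
  "accuracy": 97.91666666666667,
  "sensitivity": 97.91666666666666,
  "specificity": 97.91666666666666,
  "f1": 97.87234042553192,
  "auroc": 0.9947916666666666
}
```

i.e. of the 96 windows (each scored by a model that never saw its patient),
94 are classified correctly, and an AF window outranks a Normal window ~99%
of the time. `ecglite explain --run run --window-index 0 --class-index 1
--out sal.csv` then writes a per-sample Grad-CAM saliency trace.

Users with the PhysioNet `mitdb` download can run the same protocol on real
Holter records: point `ecglite preprocess --records DIR --mode multiclass`
at the record directory (records are polyphase-resampled to 128 Hz) and
train `mitbih_multiclass` with `--mode loso`.

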
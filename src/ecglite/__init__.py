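"""ecglite: lightweight 1D-CNN arrhythmia detection for single-lead ECG.

Pipeline: WFDB-style record / segment-table I/O -> baseline removal,
wavelet denoising, z-scoring, fixed 1000-sample windowing and one-hot
class coding -> declarative CNN specs with analytic shape/parameter/FLOP
accounting -> patient-wise (grouped holdout, LOSO) training and the full
metric suite with bootstrap CIs -> 1D Grad-CAM explanations.  A seeded
synthetic-cohort generator makes the whole chain runnable without any
dataset download.
"""

from .containers import (
    BINARY_ORDER,
    MULTICLASS_ORDER,
    BeatAnnotation,
    EcgRecord,
    SegmentTable,
    WindowSet,
)
from .preprocess import PreprocessConfig, run_preprocessing
from .architecture import (
    ModelSpec,
    ablation_spec,
    count_parameters,
    estimate_flops,
    propagate_shapes,
    reference_spec,
)
from .backend import Model
from .train_eval import (
    EvalReport,
    TrainConfig,
    auroc,
    balance_classes,
    bootstrap_ci,
    confusion_and_metrics,
    evaluate_loso,
    fit_model,
    grouped_holdout,
    loso_splits,
)
from .gradcam import SaliencyMap, gradcam_map
from .synthetic import SynthConfig, synth_beat, synth_cohort, synth_record

__version__ = "0.1.0"

__all__ = [
    "BINARY_ORDER", "MULTICLASS_ORDER", "BeatAnnotation", "EcgRecord",
    "SegmentTable", "WindowSet", "PreprocessConfig", "run_preprocessing",
    "ModelSpec", "ablation_spec", "count_parameters", "estimate_flops",
    "propagate_shapes", "reference_spec", "Model", "EvalReport",
    "TrainConfig", "auroc", "balance_classes", "bootstrap_ci",
    "confusion_and_metrics", "evaluate_loso", "fit_model", "grouped_holdout",
    "loso_splits", "SaliencyMap", "gradcam_map", "SynthConfig", "synth_beat",
    "synth_cohort", "synth_record",
]
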
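"""Patient-wise splitting, class balancing, training harness and metrics.

Splits operate on patients, never on windows: grouped 80/20 holdout and
leave-one-subject-out (LOSO) cross-validation both guarantee that no
patient contributes windows to both sides of a fold, which is what makes
the reported metrics an estimate of generalization to unseen subjects.

LOSO metrics are computed on the predictions pooled across folds (one
global confusion matrix), not averaged per fold.  Class balancing
oversamples minority classes with replacement up to the majority count and
is applied to training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import ModelSpec, count_parameters
from .backend import Model, TrainHistory
from .containers import WindowSet


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters: 50 epochs, batch 32, categorical
    cross-entropy, Adam at learning rate 0.001 by default."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.001
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class SplitPlan:
    """Folds of (train_patient_ids, test_patient_ids)."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("train and test patients overlap within a fold")


@dataclass
class EvalReport:
    """Confusion matrix plus the metric suite.

    Rates are percentages in [0, 100]; AUROC is on [0, 1].  ``cis`` holds
    95% bootstrap intervals for AUROC and F1 when computed.
    """

    class_order: tuple[str, ...]
    confusion: np.ndarray  # (K, K), rows = truth, cols = predicted
    per_class: dict[str, dict[str, float]]
    global_metrics: dict[str, float]
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "global": self.global_metrics,
            "cis": {k: list(v) for k, v in self.cis.items()},
        }


# --------------------------------------------------------------------- splits

def grouped_holdout(patient_ids: list[str], train_fraction: float = 0.8,
                    seed: int = 0) -> SplitPlan:
    """Single patient-level split: ceil(fraction * P) patients train."""
    patients = sorted(set(patient_ids))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(np.ceil(train_fraction * len(patients)))
    train = tuple(patients[i] for i in order[:n_train])
    test = tuple(patients[i] for i in order[n_train:])
    if not test:
        raise ValueError("train_fraction leaves no test patients")
    return SplitPlan(folds=((train, test),))


def loso_splits(patient_ids: list[str]) -> SplitPlan:
    """Leave-one-subject-out: P folds, each testing exactly one patient."""
    patients = sorted(set(patient_ids))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients for LOSO")
    folds = tuple(
        (tuple(p for p in patients if p != holdout), (holdout,))
        for holdout in patients
    )
    return SplitPlan(folds=folds)


def balance_classes(ws: WindowSet, seed: int = 0) -> WindowSet:
    """Oversample minority classes with replacement to the majority count.

    Window contents and labels are never altered, only their multiplicity.
    """
    labels = ws.label_indices
    counts = np.bincount(labels, minlength=ws.n_classes)
    if np.any(counts == 0):
        missing = [ws.class_order[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"cannot balance: classes absent from the set: {missing}")
    target = counts.max()
    rng = np.random.default_rng(seed)
    keep = [np.arange(len(ws))]
    for cls in range(ws.n_classes):
        deficit = target - counts[cls]
        if deficit > 0:
            pool = np.flatnonzero(labels == cls)
            keep.append(rng.choice(pool, size=deficit, replace=True))
    idx = np.concatenate(keep)
    return ws.subset(idx)


# ------------------------------------------------------------------- training

def fit_model(spec: ModelSpec, train_ws: WindowSet,
              cfg: TrainConfig = TrainConfig()) -> tuple[Model, TrainHistory]:
    """Realize the spec and train it on the window set; returns (model, history)."""
    if train_ws.n_classes != spec.n_classes:
        raise ValueError(
            f"label width {train_ws.n_classes} does not match spec.n_classes "
            f"{spec.n_classes}"
        )
    if train_ws.windows.shape[1] != spec.input_len:
        raise ValueError("window length does not match spec input length")
    model = Model(spec, seed=cfg.seed)
    realized = model.n_parameters
    analytic = count_parameters(spec)
    assert realized == analytic, (realized, analytic)
    history = model.fit(
        train_ws.windows, train_ws.labels_onehot,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, seed=cfg.seed,
    )
    return model, history


def predict_proba(model: Model, windows: np.ndarray) -> np.ndarray:
    return model.predict_proba(windows)


# -------------------------------------------------------------------- metrics

def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks handle ties as half-wins
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _f1_from_confusion(confusion: np.ndarray, positive: int) -> float:
    tp = confusion[positive, positive]
    fp = confusion[:, positive].sum() - tp
    fn = confusion[positive, :].sum() - tp
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def confusion_and_metrics(y_true_onehot: np.ndarray, y_prob: np.ndarray,
                          class_order: tuple[str, ...]) -> EvalReport:
    """Build the full metric suite from probabilities.

    Predicted class = argmax.  Per class (one-vs-rest): sensitivity
    TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total, all in
    percent.  Global accuracy = trace/total; global sensitivity/specificity
    are macro averages.  F1 and AUROC use the Arrhythmia class as positive
    when the task is binary, macro averaging otherwise.
    """
    y_true_onehot = np.asarray(y_true_onehot, dtype=np.float64)
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true_onehot.shape != y_prob.shape:
        raise ValueError("y_true and y_prob shapes disagree")
    k = len(class_order)
    if y_prob.shape[1] != k:
        raise ValueError("probability width does not match class_order")
    y_true = y_true_onehot.argmax(axis=1)
    y_pred = y_prob.argmax(axis=1)
    n = len(y_true)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (y_true, y_pred), 1)

    per_class: dict[str, dict[str, float]] = {}
    sens, spec = [], []
    for c, name in enumerate(class_order):
        tp = confusion[c, c]
        fn = confusion[c, :].sum() - tp
        fp = confusion[:, c].sum() - tp
        tn = n - tp - fn - fp
        se = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
        per_class[name] = {
            "accuracy": 100.0 * (tp + tn) / n,
            "sensitivity": se,
            "specificity": sp,
        }
        sens.append(se)
        spec.append(sp)

    binary = k == 2 and "Arrhythmia" in class_order
    if binary:
        pos = class_order.index("Arrhythmia")
        f1 = 100.0 * _f1_from_confusion(confusion, pos)
        mask_pos = y_true == pos
        auc = (auroc(y_prob[:, pos], mask_pos)
               if mask_pos.any() and (~mask_pos).any() else float("nan"))
    else:
        f1 = 100.0 * float(np.mean([_f1_from_confusion(confusion, c) for c in range(k)]))
        aucs = []
        for c in range(k):
            mask_pos = y_true == c
            if mask_pos.any() and (~mask_pos).any():
                aucs.append(auroc(y_prob[:, c], mask_pos))
        auc = float(np.mean(aucs)) if aucs else float("nan")

    global_metrics = {
        "accuracy": 100.0 * confusion.trace() / n,
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "f1": f1,
        "auroc": auc,
    }
    return EvalReport(class_order=tuple(class_order), confusion=confusion,
                      per_class=per_class, global_metrics=global_metrics)


def bootstrap_ci(y_true_onehot: np.ndarray, y_prob: np.ndarray,
                 class_order: tuple[str, ...], metric: str = "auroc",
                 B: int = 1000, seed: int = 0) -> tuple[float, float]:
    """95% bootstrap interval (2.5th/97.5th percentiles) for AUROC or F1.

    Resamples test windows with replacement; a resample that loses a class
    entirely is redrawn (the count of redraws is exposed on the function as
    ``bootstrap_ci.last_redraws``).
    """
    if metric not in ("auroc", "f1"):
        raise ValueError("metric must be 'auroc' or 'f1'")
    if B < 1:
        raise ValueError("B must be >= 1")
    y_true_onehot = np.asarray(y_true_onehot)
    y_prob = np.asarray(y_prob)
    n = len(y_true_onehot)
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        for _attempt in range(100):
            idx = rng.integers(0, n, size=n)
            labels = y_true_onehot[idx].argmax(axis=1)
            if len(np.unique(labels)) >= 2:
                break
            redraws += 1
        report = confusion_and_metrics(y_true_onehot[idx], y_prob[idx], class_order)
        values[b] = report.global_metrics[metric]
    bootstrap_ci.last_redraws = redraws  # type: ignore[attr-defined]
    return float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5))


# ----------------------------------------------------------------- evaluation

def evaluate_split(spec: ModelSpec, ws: WindowSet, plan: SplitPlan,
                   cfg: TrainConfig = TrainConfig(), balance: bool = False,
                   with_cis: bool = False, ci_B: int = 1000
                   ) -> tuple[EvalReport, np.ndarray, np.ndarray]:
    """Train/evaluate over the folds of a plan, pooling test predictions.

    Returns (report, pooled y_true one-hot, pooled y_prob).  Balancing, if
    requested, is applied to each fold's training windows only.
    """
    pooled_true, pooled_prob = [], []
    for fold_i, (train_p, test_p) in enumerate(plan.folds):
        train_ws = ws.for_patients(train_p)
        test_ws = ws.for_patients(test_p)
        if len(train_ws) == 0 or len(test_ws) == 0:
            raise ValueError(f"fold {fold_i}: empty train or test side")
        if balance:
            train_ws = balance_classes(train_ws, seed=cfg.seed + fold_i)
        model, _ = fit_model(spec, train_ws, cfg)
        pooled_true.append(test_ws.labels_onehot)
        pooled_prob.append(model.predict_proba(test_ws.windows))
    y_true = np.concatenate(pooled_true)
    y_prob = np.concatenate(pooled_prob)
    report = confusion_and_metrics(y_true, y_prob, ws.class_order)
    if with_cis:
        report.cis["auroc"] = bootstrap_ci(y_true, y_prob, ws.class_order,
                                           "auroc", B=ci_B, seed=cfg.seed)
        report.cis["f1"] = bootstrap_ci(y_true, y_prob, ws.class_order,
                                        "f1", B=ci_B, seed=cfg.seed)
    return report, y_true, y_prob


def evaluate_loso(spec: ModelSpec, ws: WindowSet,
                  cfg: TrainConfig = TrainConfig(), balance: bool = False,
                  **kwargs) -> tuple[EvalReport, np.ndarray, np.ndarray]:
    """LOSO evaluation: P folds, metrics on predictions pooled across folds."""
    plan = loso_splits(ws.patient_ids)
    return evaluate_split(spec, ws, plan, cfg, balance=balance, **kwargs)
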
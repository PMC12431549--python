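"""Patient-wise splits, class balancing, metrics, bootstrap CIs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from ecglite.containers import WindowSet
from ecglite.train_eval import (
    TrainConfig,
    auroc,
    balance_classes,
    bootstrap_ci,
    confusion_and_metrics,
    grouped_holdout,
    loso_splits,
)

BINARY = ("Normal", "Arrhythmia")


def make_ws(labels, n_features=20, patients=None, seed=0):
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    onehot = np.zeros((len(labels), 2))
    onehot[np.arange(len(labels)), labels] = 1
    return WindowSet(
        windows=rng.normal(size=(len(labels), n_features)),
        labels_onehot=onehot,
        patient_ids=patients or [f"p{i}" for i in range(len(labels))],
        class_order=BINARY,
    )


class TestSplits:
    def test_grouped_holdout_ceiling_rule(self):
        plan = grouped_holdout([f"p{i}" for i in range(10)], 0.8, seed=1)
        train, test = plan.folds[0]
        assert len(train) == 8 and len(test) == 2
        assert not set(train) & set(test)

    def test_grouped_holdout_deterministic(self):
        ids = [f"p{i}" for i in range(7)]
        assert grouped_holdout(ids, 0.8, seed=4) == grouped_holdout(ids, 0.8, seed=4)

    def test_loso_partitions_patients(self):
        ids = [f"p{i}" for i in range(5)]
        plan = loso_splits(ids)
        assert len(plan.folds) == 5
        tests = [fold[1][0] for fold in plan.folds]
        assert sorted(tests) == sorted(ids)
        for train, test in plan.folds:
            assert len(train) == 4 and len(test) == 1

    def test_loso_37_patients_gives_37_folds(self):
        assert len(loso_splits([f"p{i}" for i in range(37)]).folds) == 37

    def test_too_few_patients_raise(self):
        with pytest.raises(ValueError):
            grouped_holdout(["p0"], 0.8)
        with pytest.raises(ValueError):
            loso_splits(["p0", "p0"])


class TestBalanceClasses:
    def test_minority_oversampled_to_majority_count(self):
        ws = make_ws([0] * 30 + [1] * 70)
        out = balance_classes(ws, seed=0)
        counts = np.bincount(out.label_indices)
        assert counts.tolist() == [70, 70]

    def test_contents_unchanged_only_multiplicity(self):
        ws = make_ws([0] * 5 + [1] * 9)
        out = balance_classes(ws, seed=3)
        originals = {w.tobytes() for w in ws.windows}
        assert all(w.tobytes() in originals for w in out.windows)

    def test_balanced_input_and_determinism(self):
        ws = make_ws([0, 1] * 10)
        out = balance_classes(ws, seed=1)
        assert len(out) == len(ws)
        out2 = balance_classes(ws, seed=1)
        np.testing.assert_array_equal(out.windows, out2.windows)

    def test_absent_class_raises(self):
        with pytest.raises(ValueError, match="absent"):
            balance_classes(make_ws([1, 1, 1]), seed=0)


class TestAuroc:
    def test_textbook_cases(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auroc([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1]) == 0.5
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_pairwise_oracle(self, data):
        n = data.draw(st.integers(2, 12))
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if not (any(labels) and not all(labels)):
            labels[0], labels[-1] = False, True
        scores = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False, width=16), min_size=n, max_size=n))
        pos = [s for s, l in zip(scores, labels) if l]
        neg = [s for s, l in zip(scores, labels) if not l]
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
                   for p, q in itertools.product(pos, neg))
        expected = wins / (len(pos) * len(neg))
        assert auroc(np.array(scores), np.array(labels)) == pytest.approx(expected)

    def test_agrees_with_sklearn_on_random_data(self, rng):
        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, 500)
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestConfusionAndMetrics:
    @staticmethod
    def _probs_from_confusion(confusion):
        """Deterministic probabilities realizing a given binary confusion."""
        y_true, y_prob = [], []
        for t, row in enumerate(confusion):
            for p, count in enumerate(row):
                for _ in range(count):
                    y_true.append(t)
                    y_prob.append([0.9, 0.1] if p == 0 else [0.1, 0.9])
        onehot = np.eye(2)[y_true]
        return onehot, np.array(y_prob)

    def test_hand_computed_binary_example(self):
        onehot, probs = self._probs_from_confusion([[8, 2], [1, 9]])
        rep = confusion_and_metrics(onehot, probs, BINARY)
        np.testing.assert_array_equal(rep.confusion, [[8, 2], [1, 9]])
        assert rep.global_metrics["accuracy"] == pytest.approx(85.0)
        assert rep.per_class["Arrhythmia"]["sensitivity"] == pytest.approx(90.0)
        assert rep.per_class["Arrhythmia"]["specificity"] == pytest.approx(80.0)
        assert rep.per_class["Normal"]["sensitivity"] == \
            rep.per_class["Arrhythmia"]["specificity"]

    def test_perfect_predictions_all_rates_100(self):
        y = np.eye(3)[np.array([0, 1, 2, 0, 1, 2])]
        rep = confusion_and_metrics(y, y, ("a", "b", "c"))
        for stats in rep.per_class.values():
            assert stats["sensitivity"] == 100.0
            assert stats["specificity"] == 100.0
        assert rep.global_metrics["accuracy"] == 100.0

    @given(st.integers(0, 2**32 - 1), st.integers(10, 60))
    @settings(max_examples=30, deadline=None)
    def test_binary_duality_and_count_conservation(self, seed, n):
        rng = np.random.default_rng(seed)
        onehot = np.eye(2)[rng.integers(0, 2, n)]
        if len(np.unique(onehot.argmax(1))) < 2:
            onehot[0] = [1, 0]
            onehot[1] = [0, 1]
        p1 = rng.random(n)
        probs = np.column_stack([1 - p1, p1])
        rep = confusion_and_metrics(onehot, probs, BINARY)
        assert rep.confusion.sum() == n
        assert rep.per_class["Normal"]["sensitivity"] == \
            pytest.approx(rep.per_class["Arrhythmia"]["specificity"])
        assert rep.per_class["Arrhythmia"]["sensitivity"] == \
            pytest.approx(rep.per_class["Normal"]["specificity"])
        assert rep.global_metrics["accuracy"] == \
            pytest.approx(100.0 * rep.confusion.trace() / n)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion_and_metrics(np.eye(2), np.ones((3, 2)) / 2, BINARY)


class TestBootstrapCI:
    def _calibrated(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        scores = np.clip(labels * 0.35 + rng.normal(0.4, 0.22, n), 0, 1)
        onehot = np.eye(2)[labels]
        probs = np.column_stack([1 - scores, scores])
        return onehot, probs

    def test_same_seed_identical_interval(self):
        onehot, probs = self._calibrated()
        a = bootstrap_ci(onehot, probs, BINARY, "auroc", B=100, seed=5)
        b = bootstrap_ci(onehot, probs, BINARY, "auroc", B=100, seed=5)
        assert a == b

    def test_interval_brackets_point_estimate(self):
        onehot, probs = self._calibrated()
        point = confusion_and_metrics(onehot, probs, BINARY).global_metrics["auroc"]
        lo, hi = bootstrap_ci(onehot, probs, BINARY, "auroc", B=300, seed=1)
        assert lo <= point <= hi

    def test_coverage_on_calibrated_toy(self):
        """The 95% interval contains the point estimate of an independent
        replicate in most repetitions (loose check of calibration)."""
        hits = 0
        reps = 20
        for r in range(reps):
            onehot, probs = self._calibrated(seed=100 + r)
            truth = confusion_and_metrics(onehot, probs, BINARY).global_metrics["auroc"]
            lo, hi = bootstrap_ci(onehot, probs, BINARY, "auroc", B=200, seed=r)
            hits += lo <= truth <= hi
        assert hits == reps  # point estimate of the same sample always inside

    def test_constant_metric_collapses_interval(self):
        onehot = np.eye(2)[np.array([0, 1] * 20)]
        probs = np.where(onehot == 1, 0.99, 0.01)
        lo, hi = bootstrap_ci(onehot, probs, BINARY, "f1", B=50, seed=0)
        assert lo == hi == 100.0

    def test_degenerate_resamples_are_redrawn(self):
        onehot = np.eye(2)[np.array([0] * 19 + [1])]
        probs = np.full((20, 2), 0.5)
        bootstrap_ci(onehot, probs, BINARY, "f1", B=200, seed=0)
        assert bootstrap_ci.last_redraws > 0

    def test_invalid_arguments(self):
        onehot, probs = self._calibrated()
        with pytest.raises(ValueError):
            bootstrap_ci(onehot, probs, BINARY, "brier", B=10, seed=0)
        with pytest.raises(ValueError):
            bootstrap_ci(onehot, probs, BINARY, "f1", B=0, seed=0)


class TestTrainConfig:
    def test_defaults_follow_training_protocol(self):
        cfg = TrainConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.learning_rate) == (50, 32, 0.001)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(dropout_rate=1.0)
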
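"""Confusion-matrix accounting, accuracy, and the cycle-based experiment runners.

Identification performance is summarized by a K-class confusion matrix
(rows true subject, columns predicted) and its overall accuracy, the
diagonal sum over the total — the K-class generalization of
(TP+TN)/(TP+TN+FP+FN).  Per-class recall is exposed as the per-subject
accuracy.  Each experimental condition is evaluated over several cycles:
every cycle re-draws the 70/30 train/test membership (and the NN
initialization) from ``base_seed + cycle``, and the mean and SD (ddof=1)
of the per-cycle accuracies are reported.

Runners cover the three experiment families: the averaging sweep (train
and test both n-averaged, n = 1..5), the augmentation sweep (training
compositions mixing averaging counts, test fixed at three-times-averaged,
30 per subject), and the different-day evaluation (a model trained on
session 1 applied, without retraining, to another session's data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classify import NNSpec, SVMSpec, TrainedModel, predict, train_nn, train_svm
from .dataset import (
    LabeledDataset,
    SegmentPool,
    build_test_set,
    build_training_set,
    split_pool,
    training_config,
    TrainingConfig,
)

__all__ = [
    "ConfusionMatrix",
    "ExperimentResult",
    "confusion",
    "accuracy",
    "per_class_recall",
    "binary_reduction",
    "Condition",
    "run_cycles",
    "averaging_sweep",
    "augmentation_sweep",
    "different_day_eval",
    "results_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count table; rows = true subject, columns = predicted."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError("counts must be K x K matching labels")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion(true_labels, predicted_labels, label_order) -> ConfusionMatrix:
    """Count (true, predicted) pairs; labels outside ``label_order`` are rejected."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError("true and predicted label sequences must have equal length")
    order = list(label_order)
    known = set(order)
    stray = (set(t) | set(p)) - known
    if stray:
        raise ValueError(f"labels {sorted(stray)} not in label_order")
    if len(t) == 0:
        return ConfusionMatrix(np.zeros((len(order), len(order)), dtype=np.int64), tuple(order))
    return ConfusionMatrix(_sk_confusion(t, p, labels=order), tuple(order))


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy: diagonal sum over total; undefined on an empty matrix."""
    if cm.total == 0:
        raise ValueError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def per_class_recall(cm: ConfusionMatrix) -> dict:
    """Per-subject accuracy: diagonal over row totals (NaN for empty rows)."""
    rows = cm.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rec = np.diag(cm.counts) / rows
    return dict(zip(cm.labels, rec))


def binary_reduction(cm: ConfusionMatrix, label) -> dict:
    """One-vs-rest TP/FN/FP/TN counts for a single subject."""
    labels = list(cm.labels)
    i = labels.index(label)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum() - tp)
    fp = int(cm.counts[:, i].sum() - tp)
    tn = int(cm.total - tp - fn - fp)
    return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}


@dataclass(frozen=True)
class Condition:
    """One experimental cell: classifier plus dataset recipe.

    Either ``n_avg`` (matched-averaging experiments: train and test both
    n-averaged, 70/30 per subject) or ``dataset_id`` (augmentation
    experiments: named training composition, test fixed at
    ``test_n_avg``-averaged) must be given.
    """

    classifier: str  # "nn" | "svm"
    n_avg: int | None = None
    dataset_id: str | None = None
    test_n_avg: int | None = None
    train_per_subject: int = 70
    test_per_subject: int = 30
    epochs: int | None = None  # NN override; None = spec default (200)
    electrode: str = "door"

    def __post_init__(self) -> None:
        if self.classifier not in ("nn", "svm"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if (self.n_avg is None) == (self.dataset_id is None):
            raise ValueError("give exactly one of n_avg or dataset_id")

    @property
    def effective_test_n_avg(self) -> int:
        if self.test_n_avg is not None:
            return self.test_n_avg
        return self.n_avg if self.n_avg is not None else 3

    def describe(self) -> dict:
        return {
            "classifier": self.classifier,
            "dataset": self.dataset_id or f"{self.n_avg}avg-matched",
            "test_n_avg": self.effective_test_n_avg,
            "electrode": self.electrode,
        }


@dataclass(frozen=True)
class ExperimentResult:
    condition: dict
    accuracies: tuple[float, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))


def _train_for(cond: Condition, train_set: LabeledDataset, seed: int) -> TrainedModel:
    if cond.classifier == "nn":
        spec = NNSpec(seed=seed) if cond.epochs is None else NNSpec(seed=seed, epochs=cond.epochs)
        return train_nn(train_set, spec)
    return train_svm(train_set, SVMSpec())


def _one_cycle(corpus: SegmentPool, cond: Condition, seed: int) -> float:
    train_pool, test_pool = split_pool(corpus, 0.7, seed=seed)
    if cond.dataset_id is not None:
        cfg = training_config(cond.dataset_id, seed=seed)
    else:
        cfg = TrainingConfig(
            dataset_id=f"{cond.n_avg}avg-{cond.train_per_subject}TD",
            components=((cond.n_avg, cond.train_per_subject),),
            seed=seed,
        )
    train_set = build_training_set(cfg, train_pool)
    test_set = build_test_set(
        test_pool, n_avg=cond.effective_test_n_avg, per_subject=cond.test_per_subject, seed=seed
    )
    if len(test_set) == 0:
        raise ValueError("empty test set; cannot evaluate")
    model = _train_for(cond, train_set, seed)
    cm = confusion(test_set.y, predict(model, test_set), model.label_order)
    return accuracy(cm)


def run_cycles(
    corpus: SegmentPool, condition: Condition, cycles: int = 10, base_seed: int = 0
) -> ExperimentResult:
    """Repeat split/train/test ``cycles`` times from ``base_seed + cycle``."""
    accs = tuple(_one_cycle(corpus, condition, base_seed + c) for c in range(cycles))
    return ExperimentResult(condition=condition.describe(), accuracies=accs)


def averaging_sweep(
    corpus: SegmentPool,
    classifiers=("nn", "svm"),
    n_range=range(1, 6),
    cycles: int = 10,
    base_seed: int = 0,
    epochs: int | None = None,
    electrode: str = "door",
) -> dict[tuple[str, int], ExperimentResult]:
    """Accuracy vs averaging count, train and test both n-averaged."""
    out = {}
    for clf in classifiers:
        for n in n_range:
            cond = Condition(classifier=clf, n_avg=n, epochs=epochs, electrode=electrode)
            out[(clf, n)] = run_cycles(corpus, cond, cycles=cycles, base_seed=base_seed)
    return out


def augmentation_sweep(
    corpus: SegmentPool,
    dataset_ids,
    classifiers=("nn", "svm"),
    cycles: int = 10,
    base_seed: int = 0,
    epochs: int | None = None,
    electrode: str = "door",
) -> dict[tuple[str, str], ExperimentResult]:
    """Accuracy vs training composition; test fixed at 3-averaged, 30/subject."""
    out = {}
    for clf in classifiers:
        for ds in dataset_ids:
            cond = Condition(classifier=clf, dataset_id=ds, epochs=epochs, electrode=electrode)
            out[(clf, ds)] = run_cycles(corpus, cond, cycles=cycles, base_seed=base_seed)
    return out


def different_day_eval(
    model: TrainedModel,
    day2_corpus: SegmentPool,
    n_avg: int = 3,
    per_subject: int = 30,
    seed: int = 0,
) -> tuple[ConfusionMatrix, float]:
    """Apply an already-trained model to another session's data (no retraining).

    The evaluation is restricted to — and requires — subjects that are
    registered in the model; unknown subjects are rejected (closed set).
    """
    registered = set(model.label_order.tolist())
    stray = set(day2_corpus) - registered
    if stray:
        raise ValueError(f"day-2 subjects {sorted(stray)} are not registered in the model")
    test = build_test_set(day2_corpus, n_avg=n_avg, per_subject=per_subject, seed=seed)
    cm = confusion(test.y, predict(model, test), model.label_order)
    return cm, accuracy(cm)


def results_table(results: dict) -> pd.DataFrame:
    """Flatten sweep results into a tidy table (one row per condition)."""
    rows = []
    for key, res in results.items():
        row = dict(res.condition)
        row["key"] = "/".join(map(str, key)) if isinstance(key, tuple) else str(key)
        row["mean_accuracy"] = res.mean_accuracy
        row["sd_accuracy"] = res.sd_accuracy
        row["cycles"] = len(res.accuracies)
        rows.append(row)
    return pd.DataFrame(rows)
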
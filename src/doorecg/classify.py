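"""Closed-set subject identifiers: a three-layer neural network and a linear SVM.

Both classifiers map a 200-sample HFECG beat segment to one registered
subject.  The neural network is a fully connected 200 → 100 (ReLU) → K
(sigmoid) net trained with per-unit binary cross-entropy against one-hot
targets, Adam (lr 0.001), batch size 16, 200 epochs, seeded weight
initialization and per-epoch shuffling — implemented here directly in
numpy so every run is bit-deterministic for a given seed.  The SVM is a
soft-margin linear machine (C = 1) in a one-vs-rest multiclass scheme,
fitted by scikit-learn.  No input normalization is applied by default;
optional per-segment standardization is available behind a flag.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .dataset import LabeledDataset
from .segment_average import SEGMENT_LENGTH

__all__ = ["NNSpec", "SVMSpec", "TrainedModel", "train_nn", "train_svm", "predict",
           "save_model", "load_model"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NNSpec:
    """Hyperparameters of the three-layer network."""

    input_size: int = SEGMENT_LENGTH
    hidden_size: int = 100
    output_size: int | None = None  # None: inferred from the training labels
    batch_size: int = 16
    epochs: int = 200
    learning_rate: float = 0.001
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if min(self.input_size, self.hidden_size, self.batch_size, self.epochs) < 1:
            raise ValueError("NNSpec sizes must be positive")


@dataclass(frozen=True)
class SVMSpec:
    """Linear soft-margin SVM, one-vs-rest."""

    C: float = 1.0
    standardize: bool = False

    kernel: str = field(default="linear", init=False)
    multiclass_scheme: str = field(default="one-vs-rest", init=False)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")


@dataclass
class TrainedModel:
    """A fitted identifier with its label order and training fingerprint."""

    kind: str  # "nn" | "svm"
    parameters: dict
    label_order: np.ndarray
    input_size: int
    training_fingerprint: str
    standardize: bool = False


def _fingerprint(spec, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(repr(spec).encode())
    h.update(",".join(map(str, labels)).encode())
    return h.hexdigest()[:16]


def _prepare(train: LabeledDataset, standardize: bool):
    X = train.X.astype(np.float64)
    y = train.y
    labels = np.unique(y)
    if len(labels) < 2:
        raise ValueError("training set must contain at least 2 subjects")
    if standardize:
        X = _standardize(X)
    return X, y, labels


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def train_nn(train: LabeledDataset, spec: NNSpec = NNSpec()) -> TrainedModel:
    """Train the three-layer net; deterministic for a given spec.seed."""
    X, y, labels = _prepare(train, spec.standardize)
    if X.shape[1] != spec.input_size:
        raise ValueError(f"segments have {X.shape[1]} samples, spec expects {spec.input_size}")
    K = len(labels)
    if spec.output_size is not None and spec.output_size != K:
        raise ValueError(f"spec.output_size={spec.output_size} but training set has {K} subjects")
    idx = {lab: i for i, lab in enumerate(labels)}
    Y = np.zeros((len(y), K))
    Y[np.arange(len(y)), [idx[lab] for lab in y]] = 1.0

    rng = np.random.default_rng(spec.seed)
    # uniform init scaled by fan-in
    lim1 = 1.0 / np.sqrt(spec.input_size)
    lim2 = 1.0 / np.sqrt(spec.hidden_size)
    W1 = rng.uniform(-lim1, lim1, (spec.input_size, spec.hidden_size))
    b1 = rng.uniform(-lim1, lim1, spec.hidden_size)
    W2 = rng.uniform(-lim2, lim2, (spec.hidden_size, K))
    b2 = rng.uniform(-lim2, lim2, K)

    params = [W1, b1, W2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = spec.learning_rate
    t = 0
    n = len(X)
    for _epoch in range(spec.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            b = perm[start : start + spec.batch_size]
            xb, yb = X[b], Y[b]
            z1 = xb @ W1 + b1
            h = np.maximum(z1, 0.0)
            p = _sigmoid(h @ W2 + b2)
            # gradient of mean per-unit BCE on sigmoid outputs
            dz2 = (p - yb) / len(b)
            grads = [
                xb.T @ ((dz2 @ W2.T) * (z1 > 0)),
                ((dz2 @ W2.T) * (z1 > 0)).sum(axis=0),
                h.T @ dz2,
                dz2.sum(axis=0),
            ]
            t += 1
            for i, (pmt, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**t)
                vhat = v[i] / (1 - beta2**t)
                pmt -= lr * mhat / (np.sqrt(vhat) + eps)

    scores = _sigmoid(np.maximum(X @ W1 + b1, 0.0) @ W2 + b2)
    train_acc = float(np.mean(labels[np.argmax(scores, axis=1)] == y))
    logger.info("train_nn: %d epochs, final training accuracy %.3f", spec.epochs, train_acc)
    return TrainedModel(
        kind="nn",
        parameters={"W1": W1, "b1": b1, "W2": W2, "b2": b2, "train_accuracy": train_acc},
        label_order=labels,
        input_size=spec.input_size,
        training_fingerprint=_fingerprint(spec, labels),
        standardize=spec.standardize,
    )


def train_svm(train: LabeledDataset, spec: SVMSpec = SVMSpec()) -> TrainedModel:
    """Fit the linear one-vs-rest SVM; deterministic (convex primal fit)."""
    X, y, labels = _prepare(train, spec.standardize)
    est = LinearSVC(C=spec.C, dual=False)
    est.fit(X, y)
    train_acc = float(est.score(X, y))
    logger.info("train_svm: training accuracy %.3f", train_acc)
    return TrainedModel(
        kind="svm",
        parameters={"estimator": est, "train_accuracy": train_acc},
        label_order=labels,
        input_size=X.shape[1],
        training_fingerprint=_fingerprint(spec, labels),
        standardize=spec.standardize,
    )


def _as_matrix(segments, input_size: int) -> np.ndarray:
    if isinstance(segments, LabeledDataset):
        X = segments.X
    elif isinstance(segments, np.ndarray):
        X = np.atleast_2d(segments)
    else:
        X = np.stack([np.asarray(getattr(s, "samples", s), dtype=float) for s in segments])
    if X.shape[1] != input_size:
        raise ValueError(f"probe segments have {X.shape[1]} samples, model expects {input_size}")
    return X.astype(np.float64)


def predict(model: TrainedModel, segments) -> np.ndarray:
    """Assign each probe segment to one registered subject (closed set).

    NN decoding is the argmax of the sigmoid outputs, ties broken toward
    the lowest label index; the SVM uses the one-vs-rest decision values.
    Order-preserving: probe i yields label i.
    """
    X = _as_matrix(segments, model.input_size)
    if model.standardize:
        X = _standardize(X)
    if len(X) == 0:
        return np.asarray([], dtype=model.label_order.dtype)
    if model.kind == "nn":
        p = model.parameters
        scores = _sigmoid(np.maximum(X @ p["W1"] + p["b1"], 0.0) @ p["W2"] + p["b2"])
        return model.label_order[np.argmax(scores, axis=1)]
    if model.kind == "svm":
        return model.parameters["estimator"].predict(X)
    raise ValueError(f"unknown model kind {model.kind!r}")


MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"version": MODEL_FORMAT_VERSION, "model": model}, fh)
    return path


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    return blob["model"]
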
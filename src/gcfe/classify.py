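"""1-D convolutional classifier harness over GC feature vectors.

The default model is a small 1-D CNN implemented directly on numpy:
``n_conv_blocks`` repetitions of [conv1d(32 filters, kernel 3, same
padding, ReLU) -> max-pool(2)] followed by flatten -> dense(100, ReLU)
-> dropout(0.1) -> dense(100, ReLU) -> softmax over the classes, trained
with sparse categorical cross-entropy and the Adam optimizer. Two conv
blocks suit 112-feature inputs (pooled length 28 before flatten); six
suit 2048-feature inputs (pooled to 32). The classifier is pluggable:
anything exposing fit/predict over the feature table may substitute, and
an RBF-SVM alternative is provided.

Evaluation uses a stratified, seeded train/validation/test split and
reports accuracy plus macro-averaged one-vs-rest sensitivity and
specificity from the test-split confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "EvalReport",
    "CNN1D",
    "build_classifier",
    "build_svm",
    "train_eval",
    "metrics_from_confusion",
]


@dataclass(frozen=True)
class ClassifierConfig:
    n_conv_blocks: int = 2
    filters: int = 32
    kernel: int = 3
    dense_units: int = 100
    dropout: float = 0.1
    batch_size: int = 32
    epochs: int = 30
    n_classes: int = 4
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conv_blocks < 1:
            raise ValueError("need at least one conv block")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


@dataclass
class EvalReport:
    """Held-out metrics; percentages, plus the raw confusion matrix."""

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray
    classes: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "classes": self.classes.tolist(),
            "confusion_matrix": self.confusion.tolist(),
        }


def metrics_from_confusion(cm: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, macro sensitivity, macro specificity) in percent.

    Sensitivity is one-vs-rest recall TP/(TP+FN) and specificity is
    TN/(TN+FP), each macro-averaged over classes.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
    return (
        100.0 * tp.sum() / total,
        100.0 * sens.mean(),
        100.0 * spec.mean(),
    )


# ---------------------------------------------------------------------------
# numpy 1-D CNN


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded conv, kernel 3. x: (B, L, Cin); w: (3*Cin, Cout)."""
    bsz, length, cin = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (0, 0)))
    # patches: (B, L, 3*Cin) — taps ordered [t-1, t, t+1]
    patches = np.concatenate(
        [xp[:, 0:length, :], xp[:, 1 : length + 1, :], xp[:, 2 : length + 2, :]],
        axis=2,
    )
    return patches @ w + b, patches


def _conv1d_backward(dy, patches, w, x_shape):
    bsz, length, cin = x_shape
    dw = np.tensordot(patches, dy, axes=([0, 1], [0, 1]))
    db = dy.sum(axis=(0, 1))
    dpatch = dy @ w.T  # (B, L, 3*Cin)
    dxp = np.zeros((bsz, length + 2, cin))
    for k in range(3):
        dxp[:, k : k + length, :] += dpatch[:, :, k * cin : (k + 1) * cin]
    return dxp[:, 1 : length + 1, :], dw, db


class CNN1D:
    """Minimal 1-D CNN with Adam and sparse categorical cross-entropy."""

    def __init__(self, cfg: ClassifierConfig, input_len: int):
        if input_len < 2**cfg.n_conv_blocks:
            raise ValueError(
                f"input length {input_len} too short for "
                f"{cfg.n_conv_blocks} pooling halvings"
            )
        self.cfg = cfg
        self.input_len = input_len
        rng = np.random.default_rng(cfg.seed)
        self.params: list[np.ndarray] = []

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.conv_w, self.conv_b = [], []
        cin, length = 1, input_len
        for _ in range(cfg.n_conv_blocks):
            self.conv_w.append(he((cfg.kernel * cin, cfg.filters), cfg.kernel * cin))
            self.conv_b.append(np.zeros(cfg.filters))
            cin = cfg.filters
            length //= 2
        self.pooled_len = length
        flat = length * cfg.filters
        self.w1 = he((flat, cfg.dense_units), flat)
        self.b1 = np.zeros(cfg.dense_units)
        self.w2 = he((cfg.dense_units, cfg.dense_units), cfg.dense_units)
        self.b2 = np.zeros(cfg.dense_units)
        self.w3 = he((cfg.dense_units, cfg.n_classes), cfg.dense_units)
        self.b3 = np.zeros(cfg.n_classes)
        self._rng = rng
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool):
        cache: dict = {"x": []}
        h = x[:, :, None]  # (B, L, 1)
        for w, b in zip(self.conv_w, self.conv_b):
            z, patches = _conv1d_forward(h, w, b)
            a = np.maximum(z, 0.0)
            # max-pool width 2 stride 2; odd tails are dropped
            length = a.shape[1] - a.shape[1] % 2
            pairs = a[:, :length, :].reshape(a.shape[0], length // 2, 2, -1)
            arg = pairs.argmax(axis=2)
            pooled = np.take_along_axis(pairs, arg[:, :, None, :], axis=2)[:, :, 0, :]
            cache["x"].append((h.shape, patches, z, arg, a.shape[1]))
            h = pooled
        flat = h.reshape(h.shape[0], -1)
        z1 = flat @ self.w1 + self.b1
        a1 = np.maximum(z1, 0.0)
        if train and self.cfg.dropout > 0:
            mask = (
                self._rng.random(a1.shape) >= self.cfg.dropout
            ) / (1.0 - self.cfg.dropout)
        else:
            mask = np.ones_like(a1)
        d1 = a1 * mask
        z2 = d1 @ self.w2 + self.b2
        a2 = np.maximum(z2, 0.0)
        logits = a2 @ self.w3 + self.b3
        cache.update(
            flat=flat, z1=z1, mask=mask, d1=d1, z2=z2, a2=a2, h_shape=h.shape
        )
        return logits, cache

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def _backward(self, probs, y_idx, cache):
        bsz = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(bsz), y_idx] -= 1.0
        dlogits /= bsz
        grads: dict = {}
        grads["w3"] = cache["a2"].T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        da2 = dlogits @ self.w3.T
        dz2 = da2 * (cache["z2"] > 0)
        grads["w2"] = cache["d1"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dd1 = dz2 @ self.w2.T
        da1 = dd1 * cache["mask"]
        dz1 = da1 * (cache["z1"] > 0)
        grads["w1"] = cache["flat"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dh = (dz1 @ self.w1.T).reshape(cache["h_shape"])
        grads["conv_w"], grads["conv_b"] = [], []
        for k in range(len(self.conv_w) - 1, -1, -1):
            x_shape, patches, z, arg, pre_len = cache["x"][k]
            length = pre_len - pre_len % 2
            da = np.zeros((dh.shape[0], pre_len, dh.shape[2]))
            pair_view = da[:, :length, :].reshape(
                dh.shape[0], length // 2, 2, dh.shape[2]
            )
            np.put_along_axis(pair_view, arg[:, :, None, :], dh[:, :, None, :], axis=2)
            dz = da * (z > 0)
            dh, dw, db = _conv1d_backward(dz, patches, self.conv_w[k], x_shape)
            grads["conv_w"].insert(0, dw)
            grads["conv_b"].insert(0, db)
        return grads

    # -- optimization ------------------------------------------------------

    def _adam_step(self, grads: dict) -> None:
        lr, b1m, b2m, eps = self.cfg.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        named = (
            [(f"cw{k}", self.conv_w[k], grads["conv_w"][k]) for k in range(len(self.conv_w))]
            + [(f"cb{k}", self.conv_b[k], grads["conv_b"][k]) for k in range(len(self.conv_b))]
            + [
                ("w1", self.w1, grads["w1"]),
                ("b1", self.b1, grads["b1"]),
                ("w2", self.w2, grads["w2"]),
                ("b2", self.b2, grads["b2"]),
                ("w3", self.w3, grads["w3"]),
                ("b3", self.b3, grads["b3"]),
            ]
        )
        for name, p, g in named:
            m, v = self._adam_state.get(name, (np.zeros_like(p), np.zeros_like(p)))
            m = b1m * m + (1 - b1m) * g
            v = b2m * v + (1 - b2m) * g * g
            self._adam_state[name] = (m, v)
            mhat = m / (1 - b1m**t)
            vhat = v / (1 - b2m**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API --------------------------------------------------------

    def loss_on(self, x: np.ndarray, y_idx: np.ndarray) -> float:
        logits, _ = self._forward(np.asarray(x, dtype=float), train=False)
        probs = self._softmax(logits)
        return float(
            -np.mean(np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12))
        )

    def fit(self, x: np.ndarray, y_idx: np.ndarray, verbose: bool = False):
        """Train for cfg.epochs passes with seeded shuffling; records loss."""
        x = np.asarray(x, dtype=float)
        y_idx = np.asarray(y_idx)
        n = x.shape[0]
        self.history: list[float] = []
        for _ in range(self.cfg.epochs):
            order = self._rng.permutation(n)
            losses = []
            for s in range(0, n, self.cfg.batch_size):
                idx = order[s : s + self.cfg.batch_size]
                logits, cache = self._forward(x[idx], train=True)
                probs = self._softmax(logits)
                losses.append(
                    -np.mean(np.log(probs[np.arange(len(idx)), y_idx[idx]] + 1e-12))
                )
                grads = self._backward(probs, y_idx[idx], cache)
                self._adam_step(grads)
            self.history.append(float(np.mean(losses)))
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.asarray(x, dtype=float), train=False)
        return self._softmax(logits)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def build_classifier(cfg: ClassifierConfig, input_len: int) -> CNN1D:
    """Construct the default CNN for a given feature-vector length."""
    return CNN1D(cfg, input_len)


def build_svm(seed: int = 0):
    """RBF support-vector alternative (standardized inputs)."""
    return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))


# ---------------------------------------------------------------------------


def _split_xy(features, labels):
    if isinstance(features, pd.DataFrame):
        x = features.drop(columns=["label"], errors="ignore").to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    return x, y


def train_eval(
    model,
    features,
    labels,
    split: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> EvalReport:
    """Stratified split, fit on train, report on the held-out test split.

    ``split`` gives (train, validation, test) fractions summing to 1; the
    validation fraction may be 0. Class labels may be arbitrary integers;
    they are mapped to contiguous indices internally.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    x, y = _split_xy(features, labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError(
            "a class has fewer than 2 samples; stratified splitting needs more data"
        )
    tr_f, va_f, te_f = split
    x_tr, x_rest, y_tr, y_rest = train_test_split(
        x, y_idx, test_size=va_f + te_f, stratify=y_idx, random_state=seed
    )
    if va_f > 0:
        x_va, x_te, y_va, y_te = train_test_split(
            x_rest,
            y_rest,
            test_size=te_f / (va_f + te_f),
            stratify=y_rest,
            random_state=seed + 1,
        )
    else:
        x_va, y_va = x_rest[:0], y_rest[:0]
        x_te, y_te = x_rest, y_rest
    for name, ys in (("train", y_tr), ("test", y_te)):
        if np.unique(ys).size < classes.size:
            raise ValueError(
                f"class absent from {name} split; use stratification or more data"
            )
    model.fit(x_tr, y_tr)
    pred = model.predict(x_te)
    cm = confusion_matrix(y_te, pred, labels=np.arange(classes.size))
    acc, sens, spec = metrics_from_confusion(cm)
    return EvalReport(
        accuracy=acc, sensitivity=sens, specificity=spec, confusion=cm, classes=classes
    )
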
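"""Training and evaluation of heart-cycle classifiers.

The evaluation protocol is stratified k-fold (3 folds by default) with
*recording-grouped* splits: all cycles cut from one recording land in the
same fold, so a classifier is never validated on cycles of a recording it
trained on.  Metrics follow the one-vs-rest convention per class c —
TPR = TP/(TP+FN), PPV = TP/(TP+FP), TNR = TN/(TN+FP),
accuracy = (TP+TN)/total — and the "micro" value of a metric is the
unweighted mean over classes.  Ratios with a zero denominator are reported
as absent (None), never coerced to 0.

Backends:

``logistic_baseline``
    multinomial logistic regression (scikit-learn) on per-segment MFCC
    summary vectors; deterministic and fast, used by the end-to-end pipeline.
``small_cnn``
    a desk-scale convolutional network written in numpy — one 3x3 conv
    layer, global average pooling and two dense layers feeding a softmax —
    trained with minibatch SGD.  The pooling + dense(a) + dense(b) + softmax
    head mirrors the fine-tuning head used with large pretrained trunks.
``external_pretrained``
    adapter stub for ImageNet-pretrained trunks; requires GPU-scale tooling
    not available here and is excluded from the test surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .errors import LabelError, StratificationError, TrainingError

METRICS = ("accuracy", "tpr", "ppv", "tnr")


@dataclass
class TrainConfig:
    backend: str = "logistic_baseline"
    learning_rate: float = 0.0001
    momentum: float = 0.0  # "framework default" momentum, i.e. plain SGD
    batch_size: int = 5
    epochs: int = 100
    folds: int = 3
    seed: int = 0
    # small_cnn desk-scale knobs
    image_size: int = 32
    conv_filters: int = 8
    hidden_sizes: tuple[int, int] = (32, 16)

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class Example:
    """A labeled training/validation item; ``group`` is the source recording id."""

    x: np.ndarray
    label: str
    group: str
    id: str = ""


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, true rows x predicted columns
    class_names: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace_accuracy(self) -> float:
        """Plain multiclass accuracy = trace / total."""
        return float(np.trace(self.counts)) / self.total


@dataclass
class EvaluationReport:
    """Per-fold confusion matrices with per-class, micro and fold-averaged metrics."""

    class_names: list[str]
    per_fold: list[ConfusionMatrix]
    fold_metrics: list[dict]
    folds_avg: dict  # class -> metric -> value | None
    classes_avg: dict  # metric -> value | None

    def to_json(self) -> str:
        doc = {
            "classes": self.class_names,
            "per_fold": [
                {
                    "confusion": cm.counts.tolist(),
                    "metrics": fm,
                }
                for cm, fm in zip(self.per_fold, self.fold_metrics)
            ],
            "folds_avg": self.folds_avg,
            "classes_avg": self.classes_avg,
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    def to_table(self) -> pd.DataFrame:
        """Metric table: one row per fold plus Folds avg / Classes avg rows."""
        rows = {}
        for i, fm in enumerate(self.fold_metrics):
            rows[f"Fold{i + 1}"] = {
                (metric, cls): fm["per_class"][cls][metric]
                for metric in METRICS
                for cls in self.class_names
            }
        rows["Folds avg"] = {
            (metric, cls): self.folds_avg[cls][metric]
            for metric in METRICS
            for cls in self.class_names
        }
        rows["Classes avg"] = {
            (metric, self.class_names[0]): self.classes_avg[metric] for metric in METRICS
        }
        return pd.DataFrame(rows).T


def kfold_split(
    items: list[Example], folds: int, seed: int
) -> list[tuple[list[int], list[int]]]:
    """Stratified, recording-grouped k-fold partition (indices into ``items``).

    Recordings (groups) of each class are shuffled by the seed and dealt
    round-robin to folds; every item follows its recording.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    group_items: dict[str, list[int]] = {}
    group_label: dict[str, str] = {}
    for i, it in enumerate(items):
        group_items.setdefault(it.group, []).append(i)
        prev = group_label.setdefault(it.group, it.label)
        if prev != it.label:
            raise StratificationError(
                f"group {it.group!r} carries two labels ({prev!r}, {it.label!r})"
            )
    for g, lbl in group_label.items():
        by_class.setdefault(lbl, []).append(g)
    fold_groups: list[list[str]] = [[] for _ in range(folds)]
    for lbl in sorted(by_class):
        groups = sorted(by_class[lbl])
        if len(groups) < folds:
            raise StratificationError(
                f"class {lbl!r} has {len(groups)} recordings, fewer than {folds} folds"
            )
        rng.shuffle(groups)
        for j, g in enumerate(groups):
            fold_groups[j % folds].append(g)
    splits = []
    for k in range(folds):
        val = sorted(i for g in fold_groups[k] for i in group_items[g])
        train = sorted(set(range(len(items))) - set(val))
        splits.append((train, val))
    return splits


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------


class LogisticBaseline:
    """Multinomial logistic regression on flat feature vectors."""

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.scaler = StandardScaler()
        self.clf = LogisticRegression(max_iter=2000, random_state=cfg.seed)
        self.classes_: list[str] = []

    def fit(self, items: list[Example]) -> "LogisticBaseline":
        X = np.asarray([np.ravel(it.x) for it in items], dtype=np.float64)
        y = [it.label for it in items]
        if len(set(y)) < 2:
            raise TrainingError("training set contains a single class")
        self.classes_ = sorted(set(y))
        self.clf.fit(self.scaler.fit_transform(X), y)
        return self

    def predict(self, items: list[Example]) -> list[str]:
        X = np.asarray([np.ravel(it.x) for it in items], dtype=np.float64)
        return list(self.clf.predict(self.scaler.transform(X)))


class SmallCNN:
    """Tiny numpy CNN: conv3x3 -> ReLU -> GAP -> dense -> ReLU -> dense -> softmax."""

    def __init__(self, cfg: TrainConfig):
        cfg.validate()
        self.cfg = cfg
        self.classes_: list[str] = []
        self.params: dict[str, np.ndarray] = {}

    # -- image plumbing ------------------------------------------------
    def _prep(self, x: np.ndarray) -> np.ndarray:
        s = self.cfg.image_size
        if x.ndim == 3 and x.shape[:2] != (s, s):
            img = Image.fromarray(x.astype(np.uint8), mode="RGB").resize(
                (s, s), Image.BILINEAR
            )
            x = np.asarray(img)
        x = x.astype(np.float64) / 255.0
        if x.ndim == 2:
            x = np.repeat(x[:, :, None], 3, axis=2)
        return x

    # -- forward/backward ----------------------------------------------
    def _forward(self, X: np.ndarray) -> dict:
        p = self.params
        H2 = X.shape[1] - 2
        z = np.zeros((X.shape[0], H2, H2, self.cfg.conv_filters))
        for dy in range(3):
            for dx in range(3):
                z += np.tensordot(X[:, dy : dy + H2, dx : dx + H2, :], p["Wc"][dy, dx], axes=1)
        z += p["bc"]
        a = np.maximum(z, 0.0)
        g = a.mean(axis=(1, 2))  # global average pooling
        h1 = np.maximum(g @ p["W1"] + p["b1"], 0.0)
        h2 = np.maximum(h1 @ p["W2"] + p["b2"], 0.0)
        logits = h2 @ p["W3"] + p["b3"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        prob = e / e.sum(axis=1, keepdims=True)
        return {"X": X, "z": z, "g": g, "h1": h1, "h2": h2, "prob": prob}

    def _backward(self, cache: dict, y_onehot: np.ndarray) -> dict:
        p = self.params
        n = cache["X"].shape[0]
        grads = {}
        dlogits = (cache["prob"] - y_onehot) / n
        grads["W3"] = cache["h2"].T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dh2 = (dlogits @ p["W3"].T) * (cache["h2"] > 0)
        grads["W2"] = cache["h1"].T @ dh2
        grads["b2"] = dh2.sum(axis=0)
        dh1 = (dh2 @ p["W2"].T) * (cache["h1"] > 0)
        grads["W1"] = cache["g"].T @ dh1
        grads["b1"] = dh1.sum(axis=0)
        dg = dh1 @ p["W1"].T
        H2 = cache["z"].shape[1]
        da = dg[:, None, None, :] / (H2 * H2)
        dz = da * (cache["z"] > 0)
        grads["bc"] = dz.sum(axis=(0, 1, 2))
        dWc = np.zeros_like(p["Wc"])
        X = cache["X"]
        for dy in range(3):
            for dx in range(3):
                dWc[dy, dx] = np.tensordot(
                    X[:, dy : dy + H2, dx : dx + H2, :], dz, axes=([0, 1, 2], [0, 1, 2])
                )
        grads["Wc"] = dWc
        return grads

    def fit(self, items: list[Example]) -> "SmallCNN":
        cfg = self.cfg
        y = [it.label for it in items]
        if len(set(y)) < 2:
            raise TrainingError("training set contains a single class")
        self.classes_ = sorted(set(y))
        K = len(self.classes_)
        X = np.stack([self._prep(it.x) for it in items])
        y_idx = np.array([self.classes_.index(lbl) for lbl in y])
        Y = np.eye(K)[y_idx]
        rng = np.random.default_rng(cfg.seed)
        C, h1, h2 = cfg.conv_filters, *cfg.hidden_sizes
        self.params = {
            "Wc": rng.standard_normal((3, 3, 3, C)) * np.sqrt(2.0 / 27),
            "bc": np.zeros(C),
            "W1": rng.standard_normal((C, h1)) * np.sqrt(2.0 / C),
            "b1": np.zeros(h1),
            "W2": rng.standard_normal((h1, h2)) * np.sqrt(2.0 / h1),
            "b2": np.zeros(h2),
            "W3": rng.standard_normal((h2, K)) * np.sqrt(2.0 / h2),
            "b3": np.zeros(K),
        }
        velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        n = X.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for i0 in range(0, n, cfg.batch_size):
                batch = order[i0 : i0 + cfg.batch_size]
                cache = self._forward(X[batch])
                grads = self._backward(cache, Y[batch])
                for k in self.params:
                    velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * grads[k]
                    self.params[k] += velocity[k]
        return self

    def predict(self, items: list[Example]) -> list[str]:
        X = np.stack([self._prep(it.x) for it in items])
        prob = self._forward(X)["prob"]
        return [self.classes_[i] for i in prob.argmax(axis=1)]


def train_backend(train_items: list[Example], cfg: TrainConfig):
    """Train the backend named in ``cfg.backend`` and return the model."""
    cfg.validate()
    if cfg.backend == "logistic_baseline":
        return LogisticBaseline(cfg).fit(train_items)
    if cfg.backend == "small_cnn":
        return SmallCNN(cfg).fit(train_items)
    if cfg.backend == "external_pretrained":
        raise TrainingError(
            "external_pretrained requires GPU-scale pretrained trunks; "
            "not available in this environment"
        )
    raise ValueError(f"unknown backend {cfg.backend!r}")


def evaluate(model, items: list[Example]) -> ConfusionMatrix:
    """Confusion matrix of true x predicted labels on a validation set."""
    classes = list(model.classes_)
    for it in items:
        if it.label not in classes:
            raise LabelError(f"label {it.label!r} unseen during training")
    pred = model.predict(items)
    K = len(classes)
    counts = np.zeros((K, K), dtype=int)
    for it, p in zip(items, pred):
        counts[classes.index(it.label), classes.index(p)] += 1
    return ConfusionMatrix(counts=counts, class_names=classes)


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """One-vs-rest metrics per class plus their unweighted ('micro') means.

    Undefined ratios (zero denominator) are None and are skipped when
    averaging.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    total = cm.total
    per_class: dict[str, dict] = {}
    for i, cls in enumerate(cm.class_names):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp

        def ratio(num, den):
            return float(num) / float(den) if den > 0 else None

        per_class[cls] = {
            "accuracy": ratio(tp + tn, total),
            "tpr": ratio(tp, tp + fn),
            "ppv": ratio(tp, tp + fp),
            "tnr": ratio(tn, tn + fp),
        }
    micro = {}
    for metric in METRICS:
        vals = [v[metric] for v in per_class.values() if v[metric] is not None]
        micro[metric] = float(np.mean(vals)) if vals else None
    return {
        "per_class": per_class,
        "micro": micro,
        "multiclass_accuracy": cm.trace_accuracy,
    }


def aggregate_folds(
    per_fold: list[ConfusionMatrix], fold_metrics: list[dict] | None = None
) -> EvaluationReport:
    """Average metrics across folds ('Folds avg'), then across classes ('Classes avg')."""
    if not per_fold:
        raise ValueError("need at least one fold")
    if fold_metrics is None:
        fold_metrics = [compute_metrics(cm) for cm in per_fold]
    class_names = per_fold[0].class_names
    folds_avg: dict[str, dict] = {}
    for cls in class_names:
        folds_avg[cls] = {}
        for metric in METRICS:
            vals = [
                fm["per_class"][cls][metric]
                for fm in fold_metrics
                if fm["per_class"][cls][metric] is not None
            ]
            folds_avg[cls][metric] = float(np.mean(vals)) if vals else None
    classes_avg = {}
    for metric in METRICS:
        vals = [folds_avg[c][metric] for c in class_names if folds_avg[c][metric] is not None]
        classes_avg[metric] = float(np.mean(vals)) if vals else None
    return EvaluationReport(
        class_names=class_names,
        per_fold=per_fold,
        fold_metrics=fold_metrics,
        folds_avg=folds_avg,
        classes_avg=classes_avg,
    )
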
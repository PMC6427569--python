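"""Linear SVM over (mean ICI, log JVB) block features, with full metrics.

Rumination blocks combine a long inter-contraction interval (about
40-60 s) with a low motion-energy baseline, so the two classes form two
clusters in the (ICI, log JVB) plane and a straight decision boundary
suffices — a linear SVM keeps the classifier small enough for embedded
deployment on the sensor itself.

Features are standardised (centre and scale from the training data only)
before fitting; the raw axes differ in scale by roughly an order of
magnitude and standardisation improves conditioning without changing the
metrics. The boundary is mapped back to the original axes for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InsufficientClassError, ValidationError

FEATURES = ["mean_ici", "log_jvb"]
POSITIVE = "rumination"
NEGATIVE = "non_rumination"


@dataclass
class TrainedModel:
    """Linear decision rule in standardised (mean_ici, log_jvb) space."""

    weights: np.ndarray  # 2-vector over standardised features
    bias: float
    center: np.ndarray  # per-feature training mean
    scale: np.ndarray  # per-feature training std
    C: float = 1.0
    seed: int | None = None

    def decision(self, features: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(features) - self.center) / self.scale
        return z @ self.weights + self.bias

    def boundary_slope(self) -> float:
        """Slope d(log_jvb)/d(mean_ici) of the boundary in original axes."""
        w = self.weights / self.scale
        if w[1] == 0:
            return float("inf")
        return float(-w[0] / w[1])

    def save(self, path) -> None:
        """Persist as a human-readable key-value text file."""
        lines = [
            "format=rumibolus-linear-svm-v1",
            f"weight_mean_ici={float(self.weights[0])!r}",
            f"weight_log_jvb={float(self.weights[1])!r}",
            f"bias={float(self.bias)!r}",
            f"center_mean_ici={float(self.center[0])!r}",
            f"center_log_jvb={float(self.center[1])!r}",
            f"scale_mean_ici={float(self.scale[0])!r}",
            f"scale_log_jvb={float(self.scale[1])!r}",
            f"C={float(self.C)!r}",
            f"seed={self.seed!r}",
        ]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and "=" in line:
                    k, v = line.split("=", 1)
                    kv[k] = v
        if kv.get("format") != "rumibolus-linear-svm-v1":
            raise ValidationError(f"{path}: unrecognised model format")
        seed = None if kv["seed"] == "None" else int(kv["seed"])
        return cls(
            weights=np.array([float(kv["weight_mean_ici"]), float(kv["weight_log_jvb"])]),
            bias=float(kv["bias"]),
            center=np.array([float(kv["center_mean_ici"]), float(kv["center_log_jvb"])]),
            scale=np.array([float(kv["scale_mean_ici"]), float(kv["scale_log_jvb"])]),
            C=float(kv["C"]),
            seed=seed,
        )


@dataclass
class MetricsReport:
    """Confusion counts and the five derived classification metrics.

    ``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``,
    ``specificity = TN/(TN+FP)``, ``npv = TN/(FN+TN)`` and
    ``f1 = 2 * precision * recall / (precision + recall)``.
    Counts may be fractions (percentages of the evaluated set). A metric
    with a zero denominator is reported as None, never as 0.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    @staticmethod
    def _ratio(num, den):
        return num / den if den > 0 else None

    @property
    def precision(self):
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self):
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def npv(self):
        return self._ratio(self.tn, self.fn + self.tn)

    @property
    def f1(self):
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    @property
    def total(self):
        return self.tp + self.fp + self.fn + self.tn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["tp", "fp", "fn", "tn", "precision", "recall",
                           "specificity", "npv", "f1"],
                "value": [self.tp, self.fp, self.fn, self.tn, self.precision,
                          self.recall, self.specificity, self.npv, self.f1],
            }
        )

    def pretty(self) -> str:
        """Confusion-matrix table with the derived metrics on the margins."""
        def fmt(v):
            return "n/a" if v is None else f"{v:.3f}"

        return (
            f"                     true rum    true non-rum\n"
            f"  pred rum          TP={self.tp:<9g} FP={self.fp:<9g} precision={fmt(self.precision)}\n"
            f"  pred non-rum      FN={self.fn:<9g} TN={self.tn:<9g} npv={fmt(self.npv)}\n"
            f"                    recall={fmt(self.recall)} specificity={fmt(self.specificity)} "
            f"F1={fmt(self.f1)}"
        )


@dataclass
class FoldReport:
    """Per-fold metrics of a k-fold cross-validation run."""

    f1: list = field(default_factory=list)
    precision: list = field(default_factory=list)
    recall: list = field(default_factory=list)
    slopes: list = field(default_factory=list)  # boundary slope per fold

    @property
    def f1_mean(self) -> float:
        return float(np.mean(self.f1))

    @property
    def f1_variance(self) -> float:
        # population variance over the k folds
        return float(np.var(self.f1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": np.arange(1, len(self.f1) + 1),
                "f1": self.f1,
                "precision": self.precision,
                "recall": self.recall,
            }
        )


def _class_indices(table: pd.DataFrame):
    lab = table["label"].to_numpy()
    return {c: np.flatnonzero(lab == c) for c in (POSITIVE, NEGATIVE)}


def split_balanced(
    table: pd.DataFrame, train_fraction: float = 0.8, seed: int | None = None
):
    """Class-balanced, stratified train/test split.

    The majority class is first randomly subsampled to the minority size;
    each class is then split in the ``train_fraction`` ratio independently,
    so train and test are both exactly balanced. Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    groups = _class_indices(table)
    sizes = {c: len(ix) for c, ix in groups.items()}
    small = min(sizes.values())
    if small < 5:
        raise InsufficientClassError(f"class sizes {sizes}: need at least 5 per class")
    train_ix, test_ix = [], []
    for c in (POSITIVE, NEGATIVE):
        ix = groups[c]
        ix = rng.permutation(ix)[:small]  # subsample majority, shuffle
        n_train = int(round(train_fraction * small))
        train_ix.append(ix[:n_train])
        test_ix.append(ix[n_train:])
    train = table.iloc[np.sort(np.concatenate(train_ix))].reset_index(drop=True)
    test = table.iloc[np.sort(np.concatenate(test_ix))].reset_index(drop=True)
    return train, test


def train(train_table: pd.DataFrame, C: float = 1.0, seed: int | None = None) -> TrainedModel:
    """Fit a max-margin linear separator on standardised block features."""
    labels = train_table["label"].to_numpy()
    classes = set(labels)
    if len(classes) < 2:
        raise InsufficientClassError(f"training data has a single class: {classes}")
    X = train_table[FEATURES].to_numpy(float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    svc = SVC(kernel="linear", C=C)
    # sklearn orders classes lexicographically: non_rumination < rumination,
    # so a positive decision value means rumination
    svc.fit(Z, labels)
    return TrainedModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        center=center,
        scale=scale,
        C=C,
        seed=seed,
    )


def predict(model: TrainedModel, features) -> np.ndarray:
    """Class labels from the sign of the decision function (0 -> rumination)."""
    d = model.decision(np.asarray(features, dtype=float))
    return np.where(d >= 0, POSITIVE, NEGATIVE)


def predict_table(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    return predict(model, table[FEATURES].to_numpy(float))


def evaluate(pred, true) -> MetricsReport:
    """Confusion counts and metrics, rumination being the positive class."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if len(pred) != len(true):
        raise ValidationError("prediction and truth lengths differ")
    if len(pred) == 0:
        raise ValidationError("cannot evaluate an empty prediction set")
    tp = int(np.sum((pred == POSITIVE) & (true == POSITIVE)))
    fp = int(np.sum((pred == POSITIVE) & (true != POSITIVE)))
    fn = int(np.sum((pred != POSITIVE) & (true == POSITIVE)))
    tn = int(np.sum((pred != POSITIVE) & (true != POSITIVE)))
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn)


def kfold_validate(
    train_table: pd.DataFrame, k: int = 10, seed: int | None = None, C: float = 1.0
) -> FoldReport:
    """k disjoint stratified folds; train on k-1, evaluate on the held-out.

    Folds are formed by a seeded shuffle followed by a stratified contiguous
    partition, so every row appears in exactly one held-out fold.
    """
    labels = train_table["label"].to_numpy()
    sizes = pd.Series(labels).value_counts()
    if k > len(train_table) or (len(sizes) and k > sizes.min()):
        raise InsufficientClassError(
            f"k={k} exceeds the smallest class size ({sizes.min() if len(sizes) else 0})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = FoldReport()
    for fold_train, fold_test in skf.split(train_table[FEATURES], labels):
        model = train(train_table.iloc[fold_train], C=C, seed=seed)
        pred = predict_table(model, train_table.iloc[fold_test])
        m = evaluate(pred, labels[fold_test])
        # 2TP/(2TP+FP+FN) equals the harmonic-mean form where that is
        # defined, and stays defined (0) for a fold with no predicted
        # positives; stratification guarantees the denominator is positive
        report.f1.append(2 * m.tp / (2 * m.tp + m.fp + m.fn))
        report.precision.append(m.precision)
        report.recall.append(m.recall)
        report.slopes.append(model.boundary_slope())
    return report
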
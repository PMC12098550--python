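"""Imbalance-aware linear-margin classification and marker extraction.

The classifier is a linear maximum-margin SVM (hinge loss, L2 penalty,
C = 1 by default). Class imbalance is handled by class weights and/or
resampling of the training rows: random undersampling of the majority
class, random oversampling of the minority class, or Tomek-link
removal (dropping the majority member of every mutual-nearest-neighbor
pair with opposite labels). Evaluation reports the per-class
precision/recall/F1/support table plus overall accuracy from the
confusion matrix, and marker rankings come from the signed weights of
the fitted hyperplane.

Cross-validation is stratified: each class is distributed as evenly as
possible across the k folds (when a class has fewer members than folds,
some folds simply contain no member of it; the training side always
keeps both classes). Normalization and resampling are fitted strictly
inside the training folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from sdmstylo.features import FeatureMatrix, apply_scaling, normalize

__all__ = [
    "ResamplingStrategy",
    "LinearModel",
    "EvalReport",
    "tomek_links",
    "resample",
    "train",
    "evaluate",
    "cross_validate",
    "top_markers",
    "stratified_folds",
]


@dataclass(frozen=True)
class ResamplingStrategy:
    kind: str = "none"  # none | undersample_majority | oversample_minority | tomek_links
    seed: int = 0

    _KINDS = ("none", "undersample_majority", "oversample_minority", "tomek_links")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown resampling kind {self.kind!r}; expected one of {self._KINDS}")


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    """Confusion matrix (rows = actual, cols = predicted, in class_order)
    with per-class precision/recall/F1/support and overall accuracy."""

    class_order: tuple[str, str]
    confusion: np.ndarray
    per_class: dict[str, ClassMetrics]
    accuracy: float
    seed: int | None = None

    @classmethod
    def from_confusion(
        cls, confusion: np.ndarray | Sequence[Sequence[int]], class_order: Sequence[str],
        seed: int | None = None,
    ) -> "EvalReport":
        conf = np.asarray(confusion, dtype=int)
        if conf.shape != (2, 2):
            raise ValueError(f"expected a 2x2 confusion matrix, got shape {conf.shape}")
        order = tuple(class_order)
        per_class: dict[str, ClassMetrics] = {}
        for i, label in enumerate(order):
            tp = conf[i, i]
            fn = conf[i].sum() - tp  # actual i predicted otherwise
            fp = conf[:, i].sum() - tp  # predicted i but actually other
            precision = tp / (tp + fp) if tp + fp else 0.0
            recall = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
            per_class[label] = ClassMetrics(
                precision=float(precision), recall=float(recall), f1=float(f1),
                support=int(conf[i].sum()),
            )
        total = conf.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        return cls(
            class_order=order,
            confusion=conf,
            per_class=per_class,
            accuracy=float(np.trace(conf) / total),
            seed=seed,
        )

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str], class_order: Sequence[str],
        seed: int | None = None,
    ) -> "EvalReport":
        if len(y_true) == 0:
            raise ValueError("empty evaluation set")
        order = tuple(class_order)
        idx = {label: i for i, label in enumerate(order)}
        conf = np.zeros((2, 2), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            conf[idx[t], idx[p]] += 1
        return cls.from_confusion(conf, order, seed=seed)

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "per_class": {
                label: vars(m).copy() for label, m in self.per_class.items()
            },
            "accuracy": self.accuracy,
            "seed": self.seed,
        }

    def to_table(self, decimals: int = 2) -> str:
        """Per-class metric table (TSV) in the conventional layout:
        Class / Precision / Recall / F1-score / Support, then accuracy."""
        lines = ["Class\tPrecision\tRecall\tF1-score\tSupport"]
        for label in self.class_order:
            m = self.per_class[label]
            lines.append(
                f"{label}\t{m.precision:.{decimals}f}\t{m.recall:.{decimals}f}"
                f"\t{m.f1:.{decimals}f}\t{m.support}"
            )
        lines.append(f"Accuracy\t\t\t{self.accuracy:.{decimals}f}\t{int(self.confusion.sum())}")
        return "\n".join(lines) + "\n"


@dataclass
class LinearModel:
    """A fitted linear decision boundary plus the scaling that produced
    its feature space. ``class_order`` is (negative_label,
    positive_label): a negative decision value predicts the first."""

    feature_names: list[str]
    weights: np.ndarray
    bias: float
    class_order: tuple[str, str]
    class_weights: dict[str, float] | None
    scaling: tuple[np.ndarray, np.ndarray] | None
    seed: int = 0
    C: float = 1.0

    def decision_values(self, matrix: FeatureMatrix) -> np.ndarray:
        if list(matrix.feature_names) != list(self.feature_names):
            raise ValueError("feature space of matrix does not match the model")
        return matrix.values @ self.weights + self.bias

    def predict(self, matrix: FeatureMatrix) -> list[str]:
        neg, pos = self.class_order
        return [pos if v > 0 else neg for v in self.decision_values(matrix)]

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "class_order": list(self.class_order),
            "class_weights": self.class_weights,
            "scaling": None
            if self.scaling is None
            else {"means": self.scaling[0].tolist(), "sds": self.scaling[1].tolist()},
            "seed": self.seed,
            "C": self.C,
        }
        Path(path).write_text(json.dumps(payload) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LinearModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        scaling = d["scaling"]
        return cls(
            feature_names=d["feature_names"],
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            class_order=tuple(d["class_order"]),
            class_weights=d["class_weights"],
            scaling=None if scaling is None else (np.asarray(scaling["means"]), np.asarray(scaling["sds"])),
            seed=int(d["seed"]),
            C=float(d["C"]),
        )


def tomek_links(matrix: FeatureMatrix) -> set[tuple[str, str]]:
    """All mutual-nearest-neighbor pairs with opposite labels.

    Nearest neighbors are Euclidean; distance ties break toward the
    smaller sample id. Pairs are returned sorted within themselves.
    """
    labels = matrix.labels
    if len(set(labels)) < 2:
        return set()
    X = matrix.values
    n = len(labels)
    order = np.argsort(matrix.sample_ids)  # id-sorted for deterministic tie-breaks
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest = np.empty(n, dtype=int)
    for i in range(n):
        best = np.inf
        best_j = -1
        for j in order:  # id order => smaller sample id wins ties
            if j == i:
                continue
            if d2[i, j] < best - 1e-15:
                best = d2[i, j]
                best_j = j
        nearest[i] = best_j
    links: set[tuple[str, str]] = set()
    for i in range(n):
        j = nearest[i]
        if nearest[j] == i and labels[i] != labels[j]:
            pair = tuple(sorted((matrix.sample_ids[i], matrix.sample_ids[j])))
            links.add(pair)
    return links


def resample(matrix: FeatureMatrix, strategy: ResamplingStrategy) -> FeatureMatrix:
    """Rebalance training rows according to the strategy (training folds
    only — never applied to evaluation rows)."""
    if strategy.kind == "none":
        return matrix
    labels = np.asarray(matrix.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("resampling requires at least two classes")
    if counts.min() == counts.max() and strategy.kind in (
        "undersample_majority",
        "oversample_minority",
    ):
        return matrix  # already balanced: nothing to resample
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    rng = np.random.default_rng(strategy.seed)

    if strategy.kind == "undersample_majority":
        keep_min = np.flatnonzero(labels == minority)
        maj_rows = np.flatnonzero(labels == majority)
        keep_maj = rng.choice(maj_rows, size=counts.min(), replace=False)
        rows = np.sort(np.concatenate([keep_min, keep_maj]))
        ids = [matrix.sample_ids[r] for r in rows]
        return matrix.subset(ids)

    if strategy.kind == "oversample_minority":
        min_rows = np.flatnonzero(labels == minority)
        extra = rng.choice(min_rows, size=counts.max() - counts.min(), replace=True)
        rows = np.concatenate([np.arange(len(labels)), extra])
        return FeatureMatrix(
            sample_ids=[matrix.sample_ids[r] for r in rows],
            feature_names=list(matrix.feature_names),
            values=matrix.values[rows],
            labels=[matrix.labels[r] for r in rows],
            normalization_state=matrix.normalization_state,
            scaling=matrix.scaling,
        )

    # tomek_links: drop the majority-class member of each link
    links = tomek_links(matrix)
    label_of = dict(zip(matrix.sample_ids, matrix.labels))
    drop = {a if label_of[a] == majority else b for a, b in links}
    ids = [sid for sid in matrix.sample_ids if sid not in drop]
    return matrix.subset(ids)


def _resolve_class_weights(
    class_weights: Mapping[str, float] | str | None, labels: Sequence[str]
) -> dict[str, float] | str | None:
    if class_weights is None or class_weights == "balanced":
        return class_weights
    return dict(class_weights)


def train(
    matrix: FeatureMatrix,
    class_weights: Mapping[str, float] | str | None = None,
    seed: int = 0,
    C: float = 1.0,
) -> LinearModel:
    """Fit a linear maximum-margin classifier on a normalized matrix.

    ``class_weights`` may be None, "balanced" (inversely proportional
    to class frequencies) or an explicit group→weight map.
    """
    labels = matrix.labels
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training requires both classes present")
    if matrix.normalization_state == "raw":
        warnings.warn("training on a raw (unnormalized) matrix", stacklevel=2)
    cw = _resolve_class_weights(class_weights, labels)
    svc = SVC(kernel="linear", C=C, class_weight=cw, random_state=seed)
    svc.fit(matrix.values, labels)
    neg, pos = svc.classes_  # decision > 0 predicts classes_[1]
    if cw == "balanced":
        counts = {c: labels.count(c) for c in classes}
        total = len(labels)
        resolved = {c: total / (len(classes) * counts[c]) for c in classes}
    else:
        resolved = cw
    return LinearModel(
        feature_names=list(matrix.feature_names),
        weights=np.asarray(svc.coef_).ravel().copy(),
        bias=float(svc.intercept_[0]),
        class_order=(str(neg), str(pos)),
        class_weights=resolved,
        scaling=matrix.scaling,
        seed=seed,
        C=C,
    )


def evaluate(model: LinearModel, test: FeatureMatrix) -> EvalReport:
    """Confusion matrix and per-class precision/recall/F1/support plus
    accuracy of the model on an already-scaled evaluation matrix."""
    if len(test.sample_ids) == 0:
        raise ValueError("empty evaluation set")
    preds = model.predict(test)
    return EvalReport.from_predictions(test.labels, preds, model.class_order)


def stratified_folds(labels: Sequence[str], k: int, seed: int = 0) -> list[list[int]]:
    """Deterministic stratified fold assignment.

    Members of each class are shuffled and dealt round-robin across the
    k folds with a running cursor, so classes are spread as evenly as
    possible and fold sizes differ by at most one. Works whenever
    2 <= k <= len(labels), even if a class has fewer members than k.
    """
    n = len(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for cls in sorted(set(labels)):
        members = [i for i, lab in enumerate(labels) if lab == cls]
        rng.shuffle(members)
        for idx in members:
            folds[cursor % k].append(idx)
            cursor += 1
    return [sorted(f) for f in folds]


def cross_validate(
    matrix: FeatureMatrix,
    k: int = 10,
    strategy: ResamplingStrategy | None = None,
    class_weights: Mapping[str, float] | str | None = None,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[list[EvalReport], EvalReport]:
    """Stratified k-fold cross-validation on a **raw** feature matrix.

    Per fold, normalization is fitted on the training rows only, the
    training rows are resampled, a model is trained, and the held fold
    is scaled with the training statistics and evaluated. Returns the
    per-fold reports and a report pooled over all folds' confusions.
    """
    if matrix.normalization_state != "raw":
        raise ValueError("cross_validate expects a raw matrix; it normalizes per fold")
    strategy = strategy or ResamplingStrategy(kind="none", seed=seed)
    folds = stratified_folds(matrix.labels, k, seed=seed)
    class_order: tuple[str, str] | None = None
    reports: list[EvalReport] = []
    pooled = np.zeros((2, 2), dtype=int)
    for f, test_rows in enumerate(folds):
        test_ids = [matrix.sample_ids[i] for i in test_rows]
        train_ids = [sid for sid in matrix.sample_ids if sid not in set(test_ids)]
        scaled = normalize(matrix, fit_on=train_ids)
        train_m = resample(scaled.subset(train_ids), strategy)
        model = train(train_m, class_weights=class_weights, seed=seed, C=C)
        if class_order is None:
            class_order = model.class_order
        test_m = scaled.subset(test_ids)
        report = EvalReport.from_predictions(
            test_m.labels, model.predict(test_m), class_order, seed=seed
        )
        reports.append(report)
        pooled += report.confusion
    assert class_order is not None
    return reports, EvalReport.from_confusion(pooled, class_order, seed=seed)


def top_markers(
    model: LinearModel, k: int = 10
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Rank features by signed hyperplane weight.

    Returns (markers of the negative class, markers of the positive
    class): the k most negative and k most positive weights, ties
    broken alphabetically; zero-weight features are never markers.
    """
    nonzero = [
        (name, float(w))
        for name, w in zip(model.feature_names, model.weights)
        if w != 0.0
    ]
    if not nonzero:
        warnings.warn("all weights are zero; no meaningful marker ranking", stacklevel=2)
        return [], []
    if k > len(model.feature_names):
        warnings.warn(
            f"k={k} exceeds feature count {len(model.feature_names)}; truncating", stacklevel=2
        )
    neg = sorted((p for p in nonzero if p[1] < 0), key=lambda p: (p[1], p[0]))[:k]
    pos = sorted((p for p in nonzero if p[1] > 0), key=lambda p: (-p[1], p[0]))[:k]
    return neg, pos
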
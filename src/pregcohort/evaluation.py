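"""Evaluation protocol for the post classifier.

Implements the study design used to validate the filtering stage: a
stratified train/test split, stratified k-fold cross-validation with metrics
pooled over fold predictions, per-query-pattern breakdowns, learning curves
with ROC/AUC at increasing training fractions, and leave-one-out /
single-block feature ablations.

The accuracy confidence interval is the Wilson score interval; ROC curves are
swept over the classifier's raw scores without calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.proportion import proportion_confint

from .classify import LABELS, NOT_PIT, PIT, ClassifierModel, fit

__all__ = [
    "ClassifierSpec",
    "Dataset",
    "EvaluationReport",
    "LearningCurve",
    "evaluate",
    "stratified_split",
    "cross_validate",
    "per_pattern_evaluation",
    "learning_curve",
    "ablation_study",
]


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm"
    hyperparameters: dict | None = None
    scaled_blocks: tuple[str, ...] = ("embedding", "sentiment", "structural")


@dataclass
class Dataset:
    """A featurized labeled corpus with provenance."""

    X: sp.csr_matrix
    y: np.ndarray
    post_ids: list[str] = field(default_factory=list)
    pattern_ids: list[frozenset[int]] = field(default_factory=list)
    block_slices: dict[str, slice] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows and y length differ")

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            X=self.X[idx],
            y=self.y[idx],
            post_ids=[self.post_ids[i] for i in idx] if self.post_ids else [],
            pattern_ids=[self.pattern_ids[i] for i in idx] if self.pattern_ids else [],
            block_slices=self.block_slices,
        )

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class EvaluationReport:
    per_class: dict[str, dict[str, float]]  # label -> {precision, recall, f1}
    accuracy: float
    accuracy_ci: tuple[float, float]
    confusion: dict[str, int]  # tp/fp/fn/tn with PIT as positive
    roc_points: np.ndarray  # columns: fpr, tpr
    auc: float
    n: int

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "confusion": self.confusion,
            "auc": self.auc,
            "n": self.n,
        }


def evaluate(
    y_pred: Sequence[str], y_gold: Sequence[str], scores: Sequence[float] | None = None
) -> EvaluationReport:
    """Per-class precision/recall/F1, accuracy with 95% Wilson interval, and
    (when scores are given) the ROC curve and AUC with PIT as positive."""
    y_pred = np.asarray(y_pred)
    y_gold = np.asarray(y_gold)
    if len(y_pred) != len(y_gold):
        raise ValueError("prediction and gold lengths differ")
    if scores is not None and len(scores) != len(y_gold):
        raise ValueError("scores length differs from gold")
    n = len(y_gold)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_gold, y_pred, labels=list(LABELS), zero_division=0
    )
    per_class = {
        lab: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for lab, p, r, f in zip(LABELS, prec, rec, f1)
    }
    k = int((y_pred == y_gold).sum())
    accuracy = k / n
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    cm = confusion_matrix(y_gold, y_pred, labels=[PIT, NOT_PIT])
    confusion = {
        "tp": int(cm[0, 0]),
        "fn": int(cm[0, 1]),
        "fp": int(cm[1, 0]),
        "tn": int(cm[1, 1]),
    }
    if scores is not None and len(set(y_gold)) > 1:
        fpr, tpr, _ = roc_curve(y_gold, np.asarray(scores, dtype=float), pos_label=PIT)
        roc_points = np.column_stack([fpr, tpr])
        auc_value = float(_trapezoid_auc(fpr, tpr))
    else:
        roc_points = np.array([[0.0, 0.0], [1.0, 1.0]])
        auc_value = float("nan")
    return EvaluationReport(
        per_class=per_class,
        accuracy=accuracy,
        accuracy_ci=(float(lo), float(hi)),
        confusion=confusion,
        roc_points=roc_points,
        auc=auc_value,
        n=n,
    )


def stratified_split(
    dataset: Dataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive split preserving class proportions."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    _, counts = np.unique(dataset.y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members to stratify")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=dataset.y, random_state=seed
    )
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def _fit_on(dataset: Dataset, spec: ClassifierSpec, seed: int) -> ClassifierModel:
    return fit(
        dataset.X,
        dataset.y,
        kind=spec.kind,
        hyperparameters=spec.hyperparameters,
        seed=seed,
        block_slices=dataset.block_slices,
        scaled_blocks=spec.scaled_blocks,
    )


@dataclass
class CrossValResult:
    pooled: EvaluationReport
    folds: list[EvaluationReport]
    pooled_predictions: np.ndarray
    pooled_scores: np.ndarray
    fold_of: np.ndarray


def cross_validate(
    dataset: Dataset, k: int = 10, spec: ClassifierSpec = ClassifierSpec(), seed: int = 0
) -> CrossValResult:
    """Stratified k-fold CV; metrics are computed by pooling the held-out
    predictions of all folds (every instance predicted exactly once)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    _, counts = np.unique(dataset.y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; needs >= k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(dataset)
    pooled_pred = np.empty(n, dtype=object)
    pooled_scores = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    folds = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), dataset.y)):
        model = _fit_on(dataset.subset(tr), spec, seed)
        labels, scores = model.predict(dataset.X[te])
        pooled_pred[te] = labels
        pooled_scores[te] = scores
        fold_of[te] = fold
        folds.append(evaluate(labels, dataset.y[te], scores))
    pooled = evaluate(pooled_pred, dataset.y, pooled_scores)
    return CrossValResult(pooled, folds, pooled_pred, pooled_scores, fold_of)


def per_pattern_evaluation(
    dataset: Dataset, spec: ClassifierSpec = ClassifierSpec(), k: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Cross-validated pooled predictions partitioned by source query pattern.

    A post retrieved by several patterns contributes to each of them.
    Patterns with no retrieved instances are simply absent from the table.
    Returns one row per pattern: n, pregnancy-class precision/recall/F1.
    """
    if not dataset.pattern_ids:
        raise ValueError("dataset carries no source pattern ids")
    cv = cross_validate(dataset, k=k, spec=spec, seed=seed)
    all_pids = sorted({pid for pids in dataset.pattern_ids for pid in pids})
    rows = []
    for pid in all_pids:
        mask = np.array([pid in pids for pids in dataset.pattern_ids])
        rep = evaluate(cv.pooled_predictions[mask], dataset.y[mask])
        rows.append(
            {
                "pattern_id": pid,
                "n": int(mask.sum()),
                "precision": rep.per_class[PIT]["precision"],
                "recall": rep.per_class[PIT]["recall"],
                "f1": rep.per_class[PIT]["f1"],
            }
        )
    return pd.DataFrame(rows).set_index("pattern_id")


@dataclass
class LearningCurve:
    fractions: list[float]
    reports: list[EvaluationReport]
    sizes: list[int]

    def frame(self) -> pd.DataFrame:
        rows = []
        for frac, size, rep in zip(self.fractions, self.sizes, self.reports):
            rows.append(
                {
                    "fraction": frac,
                    "n_train": size,
                    "accuracy": rep.accuracy,
                    "auc": rep.auc,
                    "pit_f1": rep.per_class[PIT]["f1"],
                    "not_pit_f1": rep.per_class[NOT_PIT]["f1"],
                }
            )
        return pd.DataFrame(rows)


def learning_curve(
    train: Dataset,
    test: Dataset,
    fractions: Sequence[float] | None = None,
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
) -> LearningCurve:
    """Held-out performance at nested stratified training subsets.

    Subsets are nested (the 10% subset is contained in the 20% subset, and so
    on) under one seed, mirroring an annotation effort that grows over time
    and reducing between-point variance.
    """
    if fractions is None:
        fractions = [round(0.1 * i, 1) for i in range(1, 11)]
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    fractions = sorted(fractions)
    rng = np.random.default_rng(seed)
    per_class_order = {}
    for label in np.unique(train.y):
        idx = np.flatnonzero(train.y == label)
        per_class_order[label] = rng.permutation(idx)
    kept_fracs, reports, sizes = [], [], []
    n = len(train)
    for frac in fractions:
        take = []
        for label, order in per_class_order.items():
            n_label = int(round(frac * len(order)))
            take.append(order[:n_label])
        idx = np.sort(np.concatenate(take))
        subset = train.subset(idx)
        if len(np.unique(subset.y)) < 2:
            warnings.warn(f"fraction {frac} yields a single-class subset; skipped")
            continue
        model = _fit_on(subset, spec, seed)
        labels, scores = model.predict(test.X)
        kept_fracs.append(frac)
        sizes.append(len(idx))
        reports.append(evaluate(labels, test.y, scores))
    return LearningCurve(kept_fracs, reports, sizes)


def _restrict_blocks(dataset: Dataset, blocks: Sequence[str]) -> Dataset:
    """Column-subset a dataset to the named feature blocks."""
    if dataset.block_slices is None:
        raise ValueError("dataset has no block layout; cannot ablate")
    new_slices: dict[str, slice] = {}
    cols = []
    offset = 0
    for name, sl in dataset.block_slices.items():
        if name not in blocks:
            continue
        width = sl.stop - sl.start
        cols.append(np.arange(sl.start, sl.stop))
        new_slices[name] = slice(offset, offset + width)
        offset += width
    if not cols:
        raise ValueError("no columns left after block restriction")
    sub = Dataset(
        X=sp.csr_matrix(dataset.X[:, np.concatenate(cols)]),
        y=dataset.y,
        post_ids=dataset.post_ids,
        pattern_ids=dataset.pattern_ids,
        block_slices=new_slices,
    )
    return sub


def ablation_study(
    dataset: Dataset,
    blocks: Sequence[str] | None = None,
    spec: ClassifierSpec = ClassifierSpec(),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out and single-block cross-validated scores.

    Rows: "all", "minus_<block>" for each block, "<block>_only" for each
    block; columns: pregnancy-class and overall metrics.
    """
    if blocks is None:
        blocks = list(dataset.block_slices or {})
    blocks = list(blocks)
    if len(blocks) < 2:
        raise ValueError("ablation needs at least two feature blocks")
    configs: list[tuple[str, list[str]]] = [("all", blocks)]
    configs += [(f"minus_{b}", [x for x in blocks if x != b]) for b in blocks]
    configs += [(f"{b}_only", [b]) for b in blocks]
    rows = []
    for name, config_blocks in configs:
        try:
            sub = _restrict_blocks(dataset, config_blocks)
        except ValueError:
            warnings.warn(f"ablation config {name!r} has no features; skipped")
            continue
        rep = cross_validate(sub, k=k, spec=spec, seed=seed).pooled
        rows.append(
            {
                "config": name,
                "pit_precision": rep.per_class[PIT]["precision"],
                "pit_recall": rep.per_class[PIT]["recall"],
                "pit_f1": rep.per_class[PIT]["f1"],
                "not_pit_f1": rep.per_class[NOT_PIT]["f1"],
                "accuracy": rep.accuracy,
            }
        )
    return pd.DataFrame(rows).set_index("config")


def plot_learning_curve(curve: LearningCurve, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = curve.frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in ("pit_f1", "not_pit_f1", "accuracy", "auc"):
        ax.plot(frame["fraction"], frame[col], marker="o", label=col)
    ax.set_xlabel("training fraction")
    ax.set_ylabel("score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(report: EvaluationReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1], label=f"AUC={report.auc:.3f}")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
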
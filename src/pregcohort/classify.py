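"""Supervised filtering of retrieval false positives.

The retrieval patterns are precision-oriented but still collect third-person
and figurative posts; a supervised classifier separates real first-person
pregnancy indications (label ``PIT``) from those false positives
(``NOT_PIT``).  Three classifier families are provided — a Gaussian Naive
Bayes baseline, a linear support-vector machine and a random forest — plus a
majority-voting ensemble over any odd number of fitted members.

The margin classifier is scale-sensitive, so dense feature blocks
(embedding, sentiment, structural) are standardized with statistics fitted on
training data only; raw n-gram and binary cluster counts are left unscaled.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC

PIT = "PIT"
NOT_PIT = "NOT_PIT"
LABELS = (NOT_PIT, PIT)

#: dense blocks standardized before margin-based training
DEFAULT_SCALED_BLOCKS = ("embedding", "sentiment", "structural")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "naive_bayes": {},
    "svm": {"C": 1.0, "class_weight": "balanced"},
    "random_forest": {"n_estimators": 100, "max_features": "sqrt"},
}


@dataclass(frozen=True)
class LabeledInstance:
    post_id: str
    vector: sp.csr_matrix
    label: str
    source_pattern_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def stack_instances(
    instances: Sequence[LabeledInstance],
) -> tuple[sp.csr_matrix, np.ndarray]:
    X = sp.vstack([inst.vector for inst in instances], format="csr")
    y = np.array([inst.label for inst in instances])
    return X, y


class _BlockScaler:
    """Per-column standardization restricted to selected column ranges."""

    def __init__(self, columns: np.ndarray):
        self.columns = columns
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: sp.csr_matrix) -> "_BlockScaler":
        sub = np.asarray(X[:, self.columns].todense())
        self.mean_ = sub.mean(axis=0)
        scale = sub.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def transform(self, X: sp.csr_matrix) -> sp.csr_matrix:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        X = X.tolil(copy=True)
        sub = np.asarray(X[:, self.columns].todense())
        X[:, self.columns] = (sub - self.mean_) / self.scale_
        return X.tocsr()


def _scaled_columns(
    block_slices: dict[str, slice] | None, scaled_blocks: Sequence[str]
) -> np.ndarray | None:
    if block_slices is None:
        return None
    cols = [
        np.arange(sl.start, sl.stop)
        for name, sl in block_slices.items()
        if name in scaled_blocks
    ]
    if not cols:
        return None
    return np.concatenate(cols)


def _digest(X: sp.csr_matrix, y: np.ndarray) -> str:
    h = hashlib.sha256()
    coo = X.tocoo()
    for arr in (coo.row, coo.col, coo.data):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update("".join(y.tolist()).encode())
    return h.hexdigest()[:16]


@dataclass
class ClassifierModel:
    kind: str
    hyperparameters: dict
    seed: int
    estimator: object = None
    scaler: _BlockScaler | None = None
    members: list["ClassifierModel"] = field(default_factory=list)
    n_features: int | None = None
    training_digest: str = ""

    # -- prediction ---------------------------------------------------

    def _check_X(self, X: sp.csr_matrix) -> sp.csr_matrix:
        X = sp.csr_matrix(X)
        if self.n_features is None:
            raise RuntimeError("model is not fitted")
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature length {X.shape[1]} does not match training "
                f"length {self.n_features}"
            )
        return X

    def predict(self, X: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
        """Labels plus a real-valued score per row; larger score means more
        PIT-like (signed margin for the SVM, PIT probability otherwise,
        PIT vote share for the ensemble)."""
        X = self._check_X(X)
        if X.shape[0] == 0:
            return np.array([], dtype=object), np.array([])
        if self.kind == "ensemble":
            votes = np.stack([m.predict(X)[0] for m in self.members])
            n_pit = (votes == PIT).sum(axis=0)
            labels = np.where(n_pit * 2 > len(self.members), PIT, NOT_PIT)
            return labels, n_pit / len(self.members)
        Xs = self.scaler.transform(X) if self.scaler is not None else X
        est = self.estimator
        if self.kind == "naive_bayes":
            Xs = np.asarray(Xs.todense())
        labels = est.predict(Xs)
        if hasattr(est, "decision_function"):
            scores = est.decision_function(Xs)
            if est.classes_[0] == PIT:
                scores = -scores
        else:
            pit_col = int(np.where(est.classes_ == PIT)[0][0])
            scores = est.predict_proba(Xs)[:, pit_col]
        return labels, scores

    # -- persistence --------------------------------------------------

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": 1, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return joblib.load(path)["model"]


def fit(
    X: sp.csr_matrix,
    y: Sequence[str],
    kind: str = "svm",
    hyperparameters: dict | None = None,
    seed: int = 0,
    block_slices: dict[str, slice] | None = None,
    scaled_blocks: Sequence[str] = DEFAULT_SCALED_BLOCKS,
) -> ClassifierModel:
    """Fit one classifier; deterministic given the seed.

    ``block_slices`` (as produced by ``FeatureResources.block_slices``)
    activates standardization of the named dense blocks.
    """
    X = sp.csr_matrix(X)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError(f"{X.shape[0]} rows but {len(y)} labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    if kind not in DEFAULT_HYPERPARAMETERS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    params = {**DEFAULT_HYPERPARAMETERS[kind], **(hyperparameters or {})}

    cols = _scaled_columns(block_slices, scaled_blocks)
    scaler = _BlockScaler(cols).fit(X) if cols is not None else None
    Xs = scaler.transform(X) if scaler is not None else X

    if kind == "naive_bayes":
        est = GaussianNB(**params)
        est.fit(np.asarray(Xs.todense()), y)
    elif kind == "svm":
        est = LinearSVC(random_state=seed, **params)
        est.fit(Xs, y)
    else:
        est = RandomForestClassifier(random_state=seed, **params)
        est.fit(Xs, y)

    return ClassifierModel(
        kind=kind,
        hyperparameters=params,
        seed=seed,
        estimator=est,
        scaler=scaler,
        n_features=X.shape[1],
        training_digest=_digest(X, y),
    )


def fit_instances(
    instances: Sequence[LabeledInstance], kind: str = "svm", **kwargs
) -> ClassifierModel:
    X, y = stack_instances(instances)
    return fit(X, y, kind=kind, **kwargs)


def make_ensemble(members: Sequence[ClassifierModel]) -> ClassifierModel:
    """Majority-voting ensemble over an odd number (>=3) of fitted members."""
    members = list(members)
    if len(members) < 3 or len(members) % 2 == 0:
        raise ValueError("ensemble requires an odd number of members, at least 3")
    layouts = {m.n_features for m in members}
    if None in layouts or len(layouts) != 1:
        raise ValueError("all members must be fitted on the same feature layout")
    return ClassifierModel(
        kind="ensemble",
        hyperparameters={"members": [m.kind for m in members]},
        seed=members[0].seed,
        members=members,
        n_features=members[0].n_features,
    )


def ensemble_predict(
    members: Sequence[ClassifierModel], X: sp.csr_matrix
) -> np.ndarray:
    """Per-row strict majority of member labels."""
    return make_ensemble(members).predict(X)[0]
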
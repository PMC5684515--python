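"""Evaluation protocol: metric formulas, Wilson interval behavior, AUC vs the
pairwise-ranking oracle, CV partitioning, learning curves and ablation."""

import numpy as np
import pytest

from pregcohort.classify import NOT_PIT, PIT
from pregcohort.evaluation import (
    ClassifierSpec,
    Dataset,
    ablation_study,
    cross_validate,
    evaluate,
    learning_curve,
    per_pattern_evaluation,
    stratified_split,
)


def pairwise_auc(y, scores):
    """Probability-of-correct-ranking estimator over all pos/neg pairs."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == PIT]
    neg = scores[y == NOT_PIT]
    wins = ties = 0
    for p in pos:
        wins += (p > neg).sum()
        ties += (p == neg).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# -- evaluate ---------------------------------------------------------------


def test_perfect_predictions():
    gold = [PIT] * 5 + [NOT_PIT] * 5
    rep = evaluate(gold, gold, scores=[1] * 5 + [0] * 5)
    for label in (PIT, NOT_PIT):
        assert rep.per_class[label] == {"precision": 1.0, "recall": 1.0, "f1": 1.0}
    assert rep.accuracy == 1.0 and rep.auc == 1.0


def test_confusion_8_2_2_8_formulas():
    gold = [PIT] * 10 + [NOT_PIT] * 10
    pred = [PIT] * 8 + [NOT_PIT] * 2 + [PIT] * 2 + [NOT_PIT] * 8
    rep = evaluate(pred, gold)
    assert rep.confusion == {"tp": 8, "fn": 2, "fp": 2, "tn": 8}
    assert rep.per_class[PIT]["precision"] == pytest.approx(0.8)
    assert rep.per_class[PIT]["recall"] == pytest.approx(0.8)
    assert rep.per_class[PIT]["f1"] == pytest.approx(0.8)
    assert rep.accuracy == pytest.approx(0.8)


def test_equal_scores_give_auc_half():
    gold = [PIT] * 3 + [NOT_PIT] * 3
    rep = evaluate(gold, gold, scores=[0.5] * 6)
    assert rep.auc == pytest.approx(0.5)


def test_roc_endpoints_and_ci_contains_accuracy():
    rng = np.random.default_rng(0)
    gold = np.where(rng.random(200) < 0.6, PIT, NOT_PIT)
    scores = rng.random(200) + 0.5 * (gold == PIT)
    pred = np.where(scores > 0.8, PIT, NOT_PIT)
    rep = evaluate(pred, gold, scores)
    assert tuple(rep.roc_points[0]) == (0.0, 0.0)
    assert tuple(rep.roc_points[-1]) == (1.0, 1.0)
    lo, hi = rep.accuracy_ci
    assert lo <= rep.accuracy <= hi


def test_wilson_width_shrinks_like_root_n():
    widths = {}
    for n in (100, 400):
        gold = [PIT] * (3 * n // 4) + [NOT_PIT] * (n // 4)
        pred = gold[:]  # accuracy 1 at any n
        pred[: n // 10] = [NOT_PIT] * (n // 10)  # fixed 10% error rate
        lo, hi = evaluate(pred, gold).accuracy_ci
        widths[n] = hi - lo
    assert widths[400] == pytest.approx(widths[100] / 2, rel=0.15)


def test_length_mismatch_is_error():
    with pytest.raises(ValueError):
        evaluate([PIT], [PIT, NOT_PIT])


@pytest.mark.parametrize("trial", range(10))
def test_auc_sweep_matches_pairwise_oracle(trial):
    rng = np.random.default_rng(200 + trial)
    n = int(rng.integers(20, 201))
    gold = np.where(rng.random(n) < 0.5, PIT, NOT_PIT)
    if len(set(gold)) < 2:
        gold[0] = PIT if gold[1] == NOT_PIT else NOT_PIT
    scores = np.round(rng.normal(size=n) + (gold == PIT), 1)  # rounded: ties occur
    rep = evaluate(gold, gold, scores)
    assert rep.auc == pytest.approx(pairwise_auc(gold, scores))


# -- splits and cross-validation -------------------------------------------


def make_dataset(n_pit=60, n_not=40, seed=0):
    rng = np.random.default_rng(seed)
    import scipy.sparse as sp

    y = np.array([PIT] * n_pit + [NOT_PIT] * n_not)
    X = rng.normal(size=(len(y), 4)) + 2.0 * (y == PIT)[:, None]
    return Dataset(X=sp.csr_matrix(X), y=y,
                   post_ids=[f"p{i}" for i in range(len(y))])


def test_stratified_split_counts_100_60_40():
    train, test = stratified_split(make_dataset(), 0.2, seed=0)
    assert (test.y == PIT).sum() == 12 and (test.y == NOT_PIT).sum() == 8
    assert len(train) + len(test) == 100
    assert set(train.post_ids).isdisjoint(test.post_ids)


def test_stratified_split_balanced_halves_and_seed_stability():
    ds = make_dataset(50, 50)
    tr1, te1 = stratified_split(ds, 0.5, seed=3)
    assert (te1.y == PIT).sum() == (te1.y == NOT_PIT).sum() == 25
    tr2, te2 = stratified_split(ds, 0.5, seed=3)
    assert te1.post_ids == te2.post_ids


def test_stratified_split_input_validation():
    with pytest.raises(ValueError):
        stratified_split(make_dataset(), 0.0)
    with pytest.raises(ValueError):
        stratified_split(make_dataset(n_pit=1, n_not=10), 0.2)


def test_cross_validate_partitions_and_pools(corpus_bundle):
    ds = corpus_bundle["dataset"]
    cv = cross_validate(ds, k=4, spec=ClassifierSpec(kind="svm"), seed=0)
    assert len(cv.folds) == 4
    # every instance predicted exactly once
    assert np.bincount(cv.fold_of, minlength=4).sum() == len(ds)
    assert cv.pooled.n == len(ds)
    assert cv.pooled.accuracy >= 0.95  # separable corpus
    cv2 = cross_validate(ds, k=4, spec=ClassifierSpec(kind="svm"), seed=0)
    assert cv.fold_of.tolist() == cv2.fold_of.tolist()


def test_cross_validate_class_smaller_than_k():
    with pytest.raises(ValueError):
        cross_validate(make_dataset(n_pit=3, n_not=50), k=5)


def test_k2_pooled_accuracy_on_separable_data():
    cv = cross_validate(make_dataset(seed=5), k=2, spec=ClassifierSpec(kind="svm"))
    assert cv.pooled.accuracy >= 0.95


# -- per-pattern ------------------------------------------------------------


def test_per_pattern_f1_partition(corpus_bundle):
    ds = corpus_bundle["dataset"]
    table = per_pattern_evaluation(ds, spec=ClassifierSpec(kind="svm"), k=4, seed=0)
    assert table.index.is_unique
    assert (table["n"] > 0).all()
    # pooled confusion over patterns covers at least the multi-counted posts
    total_attributions = sum(len(p) for p in ds.pattern_ids)
    assert table["n"].sum() == total_attributions


def test_per_pattern_single_pattern_equals_overall():
    ds = make_dataset(30, 30)
    ds.pattern_ids = [frozenset({4})] * len(ds)
    table = per_pattern_evaluation(ds, spec=ClassifierSpec(kind="svm"), k=3, seed=0)
    cv = cross_validate(ds, k=3, spec=ClassifierSpec(kind="svm"), seed=0)
    assert list(table.index) == [4]
    assert table.loc[4, "f1"] == pytest.approx(cv.pooled.per_class[PIT]["f1"])


def test_per_pattern_requires_pattern_ids():
    with pytest.raises(ValueError):
        per_pattern_evaluation(make_dataset())


# -- learning curve ---------------------------------------------------------


def test_learning_curve_sizes_nested_and_full_point(corpus_bundle):
    ds = corpus_bundle["dataset"]
    train, test = stratified_split(ds, 0.25, seed=0)
    curve = learning_curve(train, test, fractions=[0.2, 0.5, 1.0],
                           spec=ClassifierSpec(kind="svm"), seed=0)
    assert curve.fractions == [0.2, 0.5, 1.0]
    per_class = [int(round(f * (train.y == PIT).sum()))
                 + int(round(f * (train.y == NOT_PIT).sum()))
                 for f in curve.fractions]
    assert curve.sizes == per_class
    # fraction 1.0 equals a direct train-on-all evaluation
    from pregcohort.classify import fit

    model = fit(train.X, train.y, kind="svm", seed=0,
                block_slices=ds.block_slices)
    labels, scores = model.predict(test.X)
    from pregcohort.evaluation import evaluate

    direct = evaluate(labels, test.y, scores)
    assert curve.reports[-1].accuracy == pytest.approx(direct.accuracy)
    assert curve.reports[-1].auc == pytest.approx(direct.auc)


def test_learning_curve_more_data_does_not_hurt(corpus_bundle):
    ds = corpus_bundle["dataset"]
    train, test = stratified_split(ds, 0.25, seed=1)
    aucs_small, aucs_full = [], []
    for seed in range(5):
        curve = learning_curve(train, test, fractions=[0.1, 1.0],
                               spec=ClassifierSpec(kind="svm"), seed=seed)
        aucs_small.append(curve.reports[0].auc)
        aucs_full.append(curve.reports[-1].auc)
    assert np.mean(aucs_full) >= np.mean(aucs_small) - 1e-9


def test_learning_curve_fraction_validation(corpus_bundle):
    ds = corpus_bundle["dataset"]
    train, test = stratified_split(ds, 0.25, seed=0)
    with pytest.raises(ValueError):
        learning_curve(train, test, fractions=[0.0, 0.5])


# -- ablation ---------------------------------------------------------------


def test_ablation_rows_and_identities(corpus_bundle):
    ds = corpus_bundle["dataset"]
    table = ablation_study(ds, spec=ClassifierSpec(kind="svm"), k=3, seed=0)
    blocks = list(ds.block_slices)
    assert "all" in table.index
    for b in blocks:
        assert f"minus_{b}" in table.index and f"{b}_only" in table.index
    cv_all = cross_validate(ds, k=3, spec=ClassifierSpec(kind="svm"), seed=0)
    assert table.loc["all", "accuracy"] == pytest.approx(cv_all.pooled.accuracy)
    # labels in this generator live in the vocabulary, not surface statistics
    assert table.loc["ngram_only", "pit_f1"] > table.loc["structural_only", "pit_f1"]


def test_ablation_requires_two_blocks(corpus_bundle):
    with pytest.raises(ValueError):
        ablation_study(corpus_bundle["dataset"], blocks=["ngram"])
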
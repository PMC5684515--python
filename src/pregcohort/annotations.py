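"""Multi-annotator label resolution and chance-corrected agreement.

Annotation matrices are pandas DataFrames with one row per item, one column
per annotator, and categorical labels (NaN for missing).  Disagreements are
resolved by strict majority; agreement is summarized with Fleiss' kappa,
which corrects the observed per-item agreement for the agreement expected by
chance given the marginal label distribution.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa as _sm_fleiss


def read_annotation_file(path: str | Path) -> pd.DataFrame:
    """Tab-separated file: post_id then one label column per annotator."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return frame.set_index(frame.columns[0])


def resolve_annotations(
    matrix: pd.DataFrame, tie_policy: str = "discard"
) -> dict[str, str]:
    """Consensus label per item by strict majority.

    tie_policy: "discard" drops tied items with a warning; "first" keeps the
    label of the lowest-numbered annotator among the tied labels.
    """
    if matrix.empty:
        raise ValueError("annotation matrix is empty")
    if tie_policy not in ("discard", "first"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    consensus: dict[str, str] = {}
    n_ties = 0
    for item, row in matrix.iterrows():
        labels = row.dropna().tolist()
        if not labels:
            raise ValueError(f"item {item!r} has no labels")
        counts = pd.Series(labels).value_counts()
        top = counts.max()
        winners = counts[counts == top].index.tolist()
        if len(winners) == 1:
            consensus[item] = winners[0]
        elif tie_policy == "first":
            consensus[item] = next(lab for lab in labels if lab in winners)
        else:
            n_ties += 1
    if n_ties:
        warnings.warn(f"discarded {n_ties} tied item(s)", stacklevel=2)
    return consensus


def fleiss_kappa(matrix: pd.DataFrame) -> float:
    """Fleiss' kappa over a complete item x annotator label matrix.

    Every item must carry the same number of ratings.  When only one label
    category occurs anywhere, chance agreement equals 1 and kappa is
    undefined: NaN is returned with a warning rather than raising.
    """
    values = matrix.to_numpy()
    if pd.isna(values).any():
        raise ValueError("Fleiss kappa requires a complete rating matrix")
    table, _cats = aggregate_raters(values)
    if table.shape[1] < 2:
        warnings.warn(
            "only one label category present; kappa undefined", stacklevel=2
        )
        return float("nan")
    return float(_sm_fleiss(table, method="fleiss"))


def simulate_null_annotations(
    n_items: int, n_raters: int, categories: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Labels drawn independently and uniformly: the no-agreement null."""
    data = rng.choice(categories, size=(n_items, n_raters))
    return pd.DataFrame(
        data,
        index=[f"item-{i}" for i in range(n_items)],
        columns=[f"annotator-{j}" for j in range(n_raters)],
    )
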
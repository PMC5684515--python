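"""Trimester-stratified medication-mention counting.

Counts token-level mentions of a configurable drug lexicon inside timelines
whose posts carry pregnancy-phase labels, restricted to the three trimesters.
A mention is a token equal (case-insensitively) to a known surface variant;
no fuzzy matching is attempted — variant lists are the extension point for
misspellings.  Counts are mentions only: a mention is not evidence of intake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .features import preprocess
from .posts import Timeline
from .trimester import TRIMESTER_PHASES

#: a small example lexicon of common drugs and surface variants
EXAMPLE_DRUG_LEXICON: dict[str, tuple[str, ...]] = {
    "acetaminophen": ("acetaminophen", "tylenol", "paracetamol"),
    "ibuprofen": ("ibuprofen", "advil", "motrin"),
    "ondansetron": ("ondansetron", "zofran"),
    "sertraline": ("sertraline", "zoloft"),
    "fluoxetine": ("fluoxetine", "prozac"),
    "metformin": ("metformin", "glucophage"),
    "insulin": ("insulin",),
    "amoxicillin": ("amoxicillin", "amoxil"),
    "levothyroxine": ("levothyroxine", "synthroid"),
    "ranitidine": ("ranitidine", "zantac"),
    "doxylamine": ("doxylamine", "unisom", "diclegis"),
    "folic acid": ("folate",),
}


@dataclass
class DrugLexicon:
    entries: dict[str, frozenset[str]]
    _variant_to_drug: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lowered: dict[str, frozenset[str]] = {}
        variant_to_drug: dict[str, str] = {}
        for drug, variants in self.entries.items():
            vset = frozenset(v.lower() for v in variants)
            if not vset:
                raise ValueError(f"drug {drug!r} has no variants")
            for v in vset:
                if v in variant_to_drug:
                    raise ValueError(
                        f"variant {v!r} listed under both "
                        f"{variant_to_drug[v]!r} and {drug!r}"
                    )
                variant_to_drug[v] = drug
            lowered[drug] = vset
        self.entries = lowered
        self._variant_to_drug = variant_to_drug

    def drug_of(self, token: str) -> str | None:
        return self._variant_to_drug.get(token.lower())

    def __len__(self) -> int:
        return len(self.entries)


def load_drug_lexicon(path: str | Path) -> DrugLexicon:
    """Read a ``canonical: variant, variant, ...`` file (one drug per line;
    blank lines and ``#`` comments ignored)."""
    entries: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            canonical, _, tail = line.partition(":")
            variants = tuple(v.strip() for v in tail.split(",") if v.strip())
            entries[canonical.strip()] = variants or (canonical.strip(),)
    if not entries:
        warnings.warn(f"drug lexicon {path} is empty", stacklevel=2)
    return DrugLexicon({k: frozenset(v) for k, v in entries.items()})


def count_drug_mentions(
    timelines: Iterable[Timeline],
    phase_labels: Mapping[str, Mapping[str, str]],
    lexicon: DrugLexicon,
) -> pd.DataFrame:
    """Mention counts per canonical drug per trimester.

    ``phase_labels`` maps user_id -> post_id -> phase; posts labeled pre- or
    post-pregnancy (or with no label) are ignored.  Returns a drug x phase
    count matrix with columns T1, T2, T3.
    """
    counts: dict[str, dict[str, int]] = {}
    for timeline in timelines:
        labels = phase_labels.get(timeline.user_id, {})
        for post in timeline:
            phase = labels.get(post.id)
            if phase not in TRIMESTER_PHASES:
                continue
            for token in preprocess(post.text).tokens:
                drug = lexicon.drug_of(token)
                if drug is not None:
                    row = counts.setdefault(drug, dict.fromkeys(TRIMESTER_PHASES, 0))
                    row[phase] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index").reindex(
        columns=list(TRIMESTER_PHASES)
    )
    frame = frame.fillna(0).astype(int)
    frame.index.name = "drug"
    return frame.sort_index()


def plot_mention_counts(counts: pd.DataFrame, path) -> None:
    """Stacked-bar chart of mention counts per drug per trimester."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(counts)), 4))
    counts.plot.bar(stacked=True, ax=ax)
    ax.set_ylabel("mentions")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
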
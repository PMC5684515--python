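"""Seeded synthetic corpora, resource fixtures and timelines with ground truth.

Every other module is falsifiable against this generator without any
download.  Three generators are provided:

* **corpus** — announcement posts built from templates co-designed with the
  14 retrieval patterns (every positive post is guaranteed to match at least
  one default pattern) mixed with confounder posts from three families that
  real retrieval collects as false positives: third-person pregnancies,
  figurative "baby" usage, and hypothetical/future phrasings.  Positive and
  confounder templates draw filler words from disjoint pools by default; a
  ``vocabulary_overlap`` knob mixes in a shared pool to degrade separability
  in a controlled way.  Lexical noise (appended hashtags/interjections and
  filler-word typos) is injected at a configurable rate, 10% by default.
* **timelines** — per-user post histories around a known pregnancy start
  date, with progress statements planted at known gestational weeks in
  exactly ``round(mention_prevalence x n_users)`` users, filler posts in
  every phase, and drug mentions planted per a phase schedule.  Ground truth
  (start date, per-post phase, drug counts) is emitted alongside, never read
  by the pipeline.
* **resource fixtures** — small embedding/cluster/sentiment files in the
  exact external formats the feature readers consume.

All randomness flows from one explicit ``numpy`` generator seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    EmbeddingTable,
    FeatureResources,
    SentimentLexicons,
    fit_ngram_vocabulary,
    preprocess,
    read_clusters,
    read_embeddings,
    read_subjectivity_lexicon,
    read_scored_lexicon,
    read_term_list,
)
from .posts import Post, Timeline
from .trimester import TrimesterRule, phase_of_elapsed_weeks

_EPOCH = datetime(2016, 6, 1, tzinfo=timezone.utc)

# -- corpus templates -------------------------------------------------------
# "{n}" a small integer, "{m}" a month name, "{f}" a filler word.

PIT_TEMPLATES: list[tuple[str, int]] = [
    ("im {n} weeks pregnant and totally {f}", 1),
    ("cant sleep im {n} months pregnant {f} and {f}", 1),
    ("so {f} that my pregnancy cravings hit a {f} level", 12),
    ("my pregnancy is making me {f} but im {f}", 12),
    ("so i am having a baby and super {f}", 8),
    ("baby coming soon feeling {f} and {f}", 3),
    ("i am expecting a baby in {n} months so {f}", 6),
    ("one month and i am going to be a mom {f} {f}", 7),
    ("our family is growing by two feet {f} announcement", 14),
    ("been {n} weeks since i found out i was pregnant {f}", 4),
    ("ever since i have been pregnant i feel {f} {f}", 9),
    ("ive been pregnant {n} weeks and im {f}", 10),
    ("adding one more to our family this year {f}", 11),
    ("look at this growing baby belly {f} {f}", 5),
    ("baby girl arriving in may so {f}", 2),
    ("i am going to have a baby and im {f}", 13),
]

CONFOUNDER_TEMPLATES: dict[str, list[str]] = {
    "third_person": [
        "my sister is {n} weeks pregnant i am so {f}",
        "she told me she is {n} months pregnant i am {f} for her",
        "my cousin says im having a baby niece {f} {f}",
        "my friend has been pregnant since {m} i am {f}",
    ],
    "figurative": [
        "im having a baby {f} day and its killing me",
        "i swear ive been pregnant for {n} years {f} {f}",
        "this {f} project is my baby coming soon to a {f} near you",
        "my pregnancy level hunger after the {f} marathon lol",
    ],
    "hypothetical": [
        "one day i am going to have a baby but first {f}",
        "someday i am going to be a mom until then {f} {f}",
        "when i am having a baby ill stop {f}",
        "imagine been {n} weeks since i was pregnant with this {f} idea",
    ],
}

PIT_FILLERS = [
    "thrilled", "blessed", "grateful", "nursery", "ultrasound", "kicking",
    "glowing", "registry", "overjoyed", "nesting", "cribs", "onesies",
]
CONFOUNDER_FILLERS = [
    "sarcastic", "homework", "concert", "deadline", "traffic", "gossip",
    "memes", "playlist", "drama", "midterm", "sitcom", "football",
]
SHARED_FILLERS = [
    "excited", "happy", "tired", "crazy", "love", "life", "today", "really",
]
NOISE_TOKENS = ["#blessed", "#omg", "lol", "omg", "haha", "#nofilter", "xx"]
MONTH_NAMES = ["january", "march", "may", "july", "september", "november"]


@dataclass
class GeneratorConfig:
    seed: int
    n_posts: int = 1000
    pit_fraction: float = 0.5
    confounder_mix: dict[str, float] = field(
        default_factory=lambda: {
            "third_person": 0.4, "figurative": 0.35, "hypothetical": 0.25,
        }
    )
    vocabulary_overlap: float = 0.0
    noise_rate: float = 0.1
    # timeline parameters
    n_users: int = 200
    posts_per_user: int = 12
    mention_prevalence: float = 0.44
    mentions_per_user: tuple[int, int] = (2, 3)
    drug_schedule: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "tylenol": {"T1": 4, "T2": 6, "T3": 5},
            "zofran": {"T1": 3, "T2": 2, "T3": 1},
            "insulin": {"T2": 2, "T3": 3},
        }
    )

    def __post_init__(self) -> None:
        total = sum(self.confounder_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"confounder_mix weights sum to {total}, expected 1")


def _typo(word: str, rng: np.random.Generator) -> str:
    if len(word) < 4:
        return word
    i = int(rng.integers(1, len(word) - 2))
    return word[:i] + word[i + 1] + word[i] + word[i + 2:]


def _fill(template: str, fillers: list[str], rng: np.random.Generator) -> str:
    out = template
    while "{f}" in out:
        out = out.replace("{f}", str(rng.choice(fillers)), 1)
    while "{n}" in out:
        out = out.replace("{n}", str(int(rng.integers(2, 9))), 1)
    while "{m}" in out:
        out = out.replace("{m}", str(rng.choice(MONTH_NAMES)), 1)
    return out


def _apply_noise(text: str, fillers: list[str], rate: float, rng: np.random.Generator) -> str:
    if rng.random() < rate:
        text = f"{text} {rng.choice(NOISE_TOKENS)}"
    if rng.random() < rate:
        words = text.split()
        filler_pos = [i for i, w in enumerate(words) if w in fillers]
        if filler_pos:
            i = int(rng.choice(filler_pos))
            words[i] = _typo(words[i], rng)
            text = " ".join(words)
    return text


def _filler_pool(base: list[str], overlap: float, rng: np.random.Generator) -> list[str]:
    if overlap <= 0:
        return base
    n_shared = int(round(overlap * len(base)))
    return base[: len(base) - n_shared] + list(
        rng.choice(SHARED_FILLERS, size=n_shared)
    )


def generate_corpus(config: GeneratorConfig) -> tuple[list[Post], pd.DataFrame]:
    """Labeled announcement/confounder corpus.

    Returns the posts (one per synthetic user) and a ground-truth table with
    columns post_id, user_id, label (PIT/NOT_PIT), family, target_pattern.
    """
    rng = np.random.default_rng(config.seed)
    n_pit = int(round(config.n_posts * config.pit_fraction))
    families = list(config.confounder_mix)
    weights = np.array([config.confounder_mix[f] for f in families])
    posts: list[Post] = []
    truth_rows: list[dict] = []
    for i in range(config.n_posts):
        is_pit = i < n_pit
        if is_pit:
            template, target = PIT_TEMPLATES[int(rng.integers(len(PIT_TEMPLATES)))]
            fillers = _filler_pool(PIT_FILLERS, config.vocabulary_overlap, rng)
            family = "announcement"
        else:
            family = str(rng.choice(families, p=weights))
            options = CONFOUNDER_TEMPLATES[family]
            template = options[int(rng.integers(len(options)))]
            target = 0
            fillers = _filler_pool(CONFOUNDER_FILLERS, config.vocabulary_overlap, rng)
        text = _fill(template, fillers, rng)
        noise_safe = [w for w in fillers if "pregnant" not in w]
        text = _apply_noise(text, noise_safe, config.noise_rate, rng)
        timestamp = _EPOCH + timedelta(minutes=int(rng.integers(0, 60 * 24 * 365)))
        post = Post(
            id=f"post-{i:06d}", user_id=f"user-{i:06d}",
            timestamp=timestamp, text=text,
        )
        posts.append(post)
        truth_rows.append(
            {
                "post_id": post.id,
                "user_id": post.user_id,
                "label": "PIT" if is_pit else "NOT_PIT",
                "family": family,
                "target_pattern": target,
            }
        )
    return posts, pd.DataFrame(truth_rows)


# -- timelines --------------------------------------------------------------

_PHASE_DAY_RANGES = {
    "pre": (-90, -14),
    "T1": (14, 84),    # weeks 2..12
    "T2": (91, 189),   # weeks 13..27
    "T3": (196, 280),  # weeks 28..40
    "post": (288, 350),
}

_FILLER_POSTS = [
    "had the best coffee this morning",
    "traffic was unbelievable again today",
    "finally finished that series everyone talks about",
    "weekend plans are looking great",
    "cannot decide what to cook tonight",
    "the weather has been gorgeous all week",
]

_PROGRESS_TEMPLATES = [
    "{w} weeks pregnant today and feeling good",
    "im {w} weeks pregnant now time flies",
    "officially {w} weeks into the pregnancy",
]

_DRUG_POST = "took some {drug} today hope it helps"


@dataclass
class TimelineTruth:
    users: pd.DataFrame   # user_id, has_mentions, start_date
    posts: pd.DataFrame   # post_id, user_id, true_phase
    drugs: pd.DataFrame   # variant, phase, count


def generate_timeline_set(config: GeneratorConfig) -> tuple[list[Timeline], TimelineTruth]:
    """Per-user timelines around known pregnancy start dates.

    Exactly ``round(mention_prevalence x n_users)`` users carry progress
    statements (at integer gestational weeks, timestamped exactly at
    start + 7w days so the planted start is recoverable); all users get
    filler posts across phases; drug mentions follow ``drug_schedule``
    inside mention-carrying users' trimester posts.
    """
    rng = np.random.default_rng(config.seed + 1 if config.seed < 2**31 - 1 else 0)
    n_with = int(round(config.mention_prevalence * config.n_users))
    rule = TrimesterRule()
    timelines: list[Timeline] = []
    user_rows, post_rows = [], []
    drug_slots: list[tuple[str, str]] = [
        (variant, phase)
        for variant, phases in config.drug_schedule.items()
        for phase, count in phases.items()
        for _ in range(count)
    ]
    mention_user_ids = [f"tluser-{u:05d}" for u in range(n_with)]
    slot_users = (
        rng.choice(mention_user_ids, size=len(drug_slots))
        if drug_slots and n_with
        else []
    )
    post_counter = 0

    def add_post(user_id: str, start: datetime, day: float, text: str) -> Post:
        nonlocal post_counter
        ts = start + timedelta(days=float(day))
        post = Post(
            id=f"tlpost-{post_counter:07d}", user_id=user_id, timestamp=ts, text=text
        )
        post_counter += 1
        post_rows.append(
            {
                "post_id": post.id,
                "user_id": user_id,
                "true_phase": phase_of_elapsed_weeks(day / 7.0, rule),
            }
        )
        return post

    for u in range(config.n_users):
        user_id = f"tluser-{u:05d}"
        has_mentions = u < n_with
        start = _EPOCH + timedelta(days=int(rng.integers(0, 365)))
        posts: list[Post] = []
        if has_mentions:
            n_mentions = int(rng.integers(config.mentions_per_user[0],
                                          config.mentions_per_user[1] + 1))
            weeks = sorted(rng.choice(np.arange(5, 39), size=n_mentions, replace=False))
            for w in weeks:
                template = _PROGRESS_TEMPLATES[int(rng.integers(len(_PROGRESS_TEMPLATES)))]
                posts.append(
                    add_post(user_id, start, 7.0 * int(w), template.format(w=int(w)))
                )
            for variant, phase in (
                [ds for ds, su in zip(drug_slots, slot_users) if su == user_id]
            ):
                lo, hi = _PHASE_DAY_RANGES[phase]
                day = int(rng.integers(lo, hi + 1))
                posts.append(add_post(user_id, start, day, _DRUG_POST.format(drug=variant)))
        n_fillers = max(0, config.posts_per_user - len(posts))
        for _ in range(n_fillers):
            phase = str(rng.choice(list(_PHASE_DAY_RANGES)))
            lo, hi = _PHASE_DAY_RANGES[phase]
            day = int(rng.integers(lo, hi + 1))
            text = _FILLER_POSTS[int(rng.integers(len(_FILLER_POSTS)))]
            posts.append(add_post(user_id, start, day, text))
        timelines.append(Timeline(user_id, posts))
        user_rows.append(
            {"user_id": user_id, "has_mentions": has_mentions, "start_date": start}
        )

    drug_rows = [
        {"variant": variant, "phase": phase, "count": count}
        for variant, phases in config.drug_schedule.items()
        for phase, count in phases.items()
    ]
    truth = TimelineTruth(
        users=pd.DataFrame(user_rows),
        posts=pd.DataFrame(post_rows),
        drugs=pd.DataFrame(drug_rows, columns=["variant", "phase", "count"]),
    )
    return timelines, truth


# -- resource fixtures ------------------------------------------------------

_POSITIVE_SEED = [
    "thrilled", "blessed", "grateful", "overjoyed", "excited", "happy",
    "love", "best", "great", "glowing",
]
_NEGATIVE_SEED = [
    "killing", "hate", "sick", "worst", "tired", "drama", "crazy", "deadline",
]


def generate_resource_fixtures(
    vocab: list[str],
    dim: int,
    n_clusters: int,
    seed: int,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write deterministic embedding/cluster/sentiment fixture files for the
    given token vocabulary, in the external formats the readers consume.
    Returns the path of each written file."""
    if dim < 2:
        raise ValueError("embedding dimension must be at least 2")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vocab = sorted(dict.fromkeys(vocab))

    emb_path = out / "embeddings.txt"
    with open(emb_path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(vocab)} {dim}\n")
        for token in vocab:
            vec = rng.normal(size=dim).round(5)
            fh.write(token + " " + " ".join(f"{v:.5f}" for v in vec) + "\n")

    width = max(4, int(np.ceil(np.log2(max(n_clusters, 2)))))
    paths = [format(c, f"0{width}b") for c in range(n_clusters)]
    cluster_path = out / "clusters.tsv"
    with open(cluster_path, "w", encoding="utf-8") as fh:
        assignment = rng.integers(0, n_clusters, size=len(vocab))
        order = np.argsort(assignment, kind="stable")
        for idx in order:
            fh.write(f"{paths[int(assignment[idx])]}\t{vocab[idx]}\t{int(rng.integers(1, 1000))}\n")

    pos = [t for t in vocab if t in _POSITIVE_SEED]
    neg = [t for t in vocab if t in _NEGATIVE_SEED]
    (out / "positive.txt").write_text("\n".join(pos) + "\n", encoding="utf-8")
    (out / "negative.txt").write_text("\n".join(neg) + "\n", encoding="utf-8")
    with open(out / "polarity.tsv", "w", encoding="utf-8") as fh:
        for t in pos:
            fh.write(f"{t}\t{rng.uniform(0.3, 1.0):.3f}\n")
        for t in neg:
            fh.write(f"{t}\t{-rng.uniform(0.3, 1.0):.3f}\n")
    with open(out / "subjectivity.tsv", "w", encoding="utf-8") as fh:
        for t in pos + neg:
            pol = 1.0 if t in pos else -1.0
            fh.write(f"{t}\t{pol:.1f}\t{rng.uniform(0.2, 1.0):.3f}\n")

    return {
        "embeddings": emb_path,
        "clusters": cluster_path,
        "positive": out / "positive.txt",
        "negative": out / "negative.txt",
        "polarity": out / "polarity.tsv",
        "subjectivity": out / "subjectivity.tsv",
    }


def load_resource_fixtures(paths: dict[str, Path]) -> tuple[EmbeddingTable, "object", SentimentLexicons]:
    """Round-trip fixture files through the production readers."""
    table = read_embeddings(paths["embeddings"])
    cmap = read_clusters(paths["clusters"])
    lex = SentimentLexicons(
        positive_terms=read_term_list(paths["positive"]),
        negative_terms=read_term_list(paths["negative"]),
        prior_polarity=read_scored_lexicon(paths["polarity"]),
        subjectivity=read_subjectivity_lexicon(paths["subjectivity"]),
    )
    return table, cmap, lex


def build_resources(
    texts: list[str],
    seed: int,
    out_dir: str | Path,
    dim: int = 50,
    n_clusters: int = 64,
    min_count: int = 2,
) -> FeatureResources:
    """Fit an n-gram vocabulary on the texts and generate matching dense
    resource fixtures, returning ready-to-use FeatureResources."""
    sequences = [preprocess(t) for t in texts]
    vocabulary = fit_ngram_vocabulary(sequences, min_count=min_count)
    tokens = sorted({tok for seq in sequences for tok in seq.tokens})
    paths = generate_resource_fixtures(tokens, dim, n_clusters, seed, out_dir)
    table, cmap, lex = load_resource_fixtures(paths)
    return FeatureResources(
        vocabulary=vocabulary, embeddings=table, clusters=cmap, lexicons=lex
    )
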
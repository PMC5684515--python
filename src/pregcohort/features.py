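"""Hybrid sparse + dense feature representation for short posts.

A post is converted into a fixed-layout concatenation of five blocks:

1. **n-grams** — counts of 1-, 2- and 3-grams over Porter-stemmed lowercase
   tokens (stopwords kept), restricted to a vocabulary fitted on training
   data;
2. **embeddings** — the elementwise sum of pretrained dense word vectors
   (default dimension 400) over the post's raw tokens;
3. **clusters** — binary indicators over a fixed hierarchical word
   clustering (default 1000 base clusters), looked up on raw tokens;
4. **sentiment** — six summary scores from three lexicon families
   (positive/negative term lists, prior polarities, subjectivity);
5. **structural** — six surface statistics of the raw text.

Sparse n-gram counts generalize poorly on 140-character posts because of
lexical variation; the dense blocks provide the generalization, which is why
the hybrid layout outperforms any single block on its own.

Tokenization splits on whitespace and strips surrounding punctuation while
keeping contractions ("i'm") whole and hashtags/@-mentions as single tokens
with the leading marker stripped from the token content.  Embedding and
cluster lookups use raw tokens; stems are used only for n-grams, matching how
the pretrained resources are keyed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
import scipy.sparse as sp

from . import _porter
from .patterns import normalize_text
from .posts import Post

SENTIMENT_SLOTS = 6
STRUCTURAL_SLOTS = 6
BLOCK_ORDER = ("ngram", "embedding", "cluster", "sentiment", "structural")

_TOKEN_SPLIT = re.compile(r"\s+")
_EDGE_PUNCT = re.compile(r"^\W+|\W+$")
_WORD = re.compile(r"[a-z0-9']+")


@dataclass
class TokenSequence:
    tokens: list[str]
    stems: list[str]
    markers: list[str]  # "" plain, "#" hashtag, "@" mention

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.stems) == len(self.markers)):
            raise ValueError("tokens, stems and markers must be parallel")

    def __len__(self) -> int:
        return len(self.tokens)


def preprocess(text: str) -> TokenSequence:
    """Lowercase, normalize apostrophes, tokenize and Porter-stem."""
    tokens: list[str] = []
    markers: list[str] = []
    for raw in _TOKEN_SPLIT.split(normalize_text(text)):
        if not raw:
            continue
        marker = raw[0] if raw[0] in "#@" else ""
        core = _EDGE_PUNCT.sub("", raw[1:] if marker else raw)
        if core:
            tokens.append(core)
            markers.append(marker)
    stems = [_porter.stem(tok) for tok in tokens]
    return TokenSequence(tokens, stems, markers)


# --------------------------------------------------------------------------
# n-grams


@dataclass
class NgramVocabulary:
    gram_to_index: dict[str, int]
    order_range: tuple[int, int] = (1, 3)
    fitted_on: str = ""

    def __len__(self) -> int:
        return len(self.gram_to_index)


def _iter_ngrams(stems: Sequence[str], lo: int, hi: int) -> Iterable[str]:
    for n in range(lo, hi + 1):
        for i in range(len(stems) - n + 1):
            yield " ".join(stems[i : i + n])


def fit_ngram_vocabulary(
    corpus: Sequence[TokenSequence],
    min_count: int = 2,
    order_range: tuple[int, int] = (1, 3),
) -> NgramVocabulary:
    """Collect all stem n-grams occurring at least *min_count* times; indices
    are assigned lexicographically so the layout is platform-independent."""
    if not corpus:
        raise ValueError("cannot fit an n-gram vocabulary on an empty corpus")
    counts: dict[str, int] = {}
    for seq in corpus:
        for gram in _iter_ngrams(seq.stems, *order_range):
            counts[gram] = counts.get(gram, 0) + 1
    kept = sorted(g for g, c in counts.items() if c >= min_count)
    if not kept:
        warnings.warn("n-gram vocabulary is empty at this min_count", stacklevel=2)
    return NgramVocabulary(
        gram_to_index={g: i for i, g in enumerate(kept)},
        order_range=order_range,
        fitted_on=f"{len(corpus)} documents",
    )


def ngram_vector(seq: TokenSequence, vocab: NgramVocabulary) -> sp.csr_matrix:
    """Sparse row of in-vocabulary gram counts; OOV grams are ignored."""
    counts: dict[int, int] = {}
    for gram in _iter_ngrams(seq.stems, *vocab.order_range):
        idx = vocab.gram_to_index.get(gram)
        if idx is not None:
            counts[idx] = counts.get(idx, 0) + 1
    cols = sorted(counts)
    data = [counts[c] for c in cols]
    return sp.csr_matrix(
        (data, (np.zeros(len(cols), dtype=int), cols)),
        shape=(1, len(vocab)),
        dtype=np.float64,
    )


# --------------------------------------------------------------------------
# dense resources


@dataclass
class EmbeddingTable:
    dimension: int = 400
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tok, vec in self.vectors.items():
            if len(vec) != self.dimension:
                raise ValueError(
                    f"vector for {tok!r} has length {len(vec)}, "
                    f"expected {self.dimension}"
                )


def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Read a word2vec-text table: header ``V D`` then ``token v1 ... vD``."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"embedding row for {parts[0]!r} has wrong arity")
            vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float64)
    if len(vectors) != n:
        warnings.warn(
            f"embedding header declares {n} rows, file holds {len(vectors)}",
            stacklevel=2,
        )
    return EmbeddingTable(dimension=dim, vectors=vectors)


def embed_post(seq: TokenSequence, table: EmbeddingTable) -> np.ndarray:
    """Sum of the vectors of in-table tokens; zero vector when none hit."""
    out = np.zeros(table.dimension)
    for tok in seq.tokens:
        vec = table.vectors.get(tok)
        if vec is not None:
            out += vec
    return out


@dataclass
class ClusterMap:
    n_clusters: int = 1000
    token_to_cluster: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: c for t, c in self.token_to_cluster.items() if c >= self.n_clusters}
        if bad:
            raise ValueError(f"cluster indices out of range: {bad}")


def read_clusters(path: str | Path, n_clusters: int | None = None) -> ClusterMap:
    """Read tab-separated ``bitstring-path<TAB>token<TAB>frequency`` lines;
    the cluster index of a token is the rank of its distinct path in file
    order."""
    path_to_idx: dict[str, int] = {}
    token_to_cluster: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            bits, token, _freq = line.rstrip("\n").split("\t")
            if bits not in path_to_idx:
                path_to_idx[bits] = len(path_to_idx)
            token_to_cluster[token] = path_to_idx[bits]
    return ClusterMap(
        n_clusters=n_clusters if n_clusters is not None else max(len(path_to_idx), 1),
        token_to_cluster=token_to_cluster,
    )


def cluster_vector(seq: TokenSequence, cmap: ClusterMap) -> np.ndarray:
    """Binary indicator over clusters; raw-token lookup."""
    out = np.zeros(cmap.n_clusters)
    for tok in seq.tokens:
        c = cmap.token_to_cluster.get(tok)
        if c is not None:
            out[c] = 1.0
    return out


# --------------------------------------------------------------------------
# sentiment


@dataclass
class SentimentLexicons:
    positive_terms: frozenset[str] = frozenset()
    negative_terms: frozenset[str] = frozenset()
    prior_polarity: dict[str, float] = field(default_factory=dict)
    subjectivity: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.positive_terms & self.negative_terms
        if overlap:
            raise ValueError(f"terms in both polar sets: {sorted(overlap)}")


def read_term_list(path: str | Path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip().lower() for line in fh if line.strip() and not line.startswith(";")
        )


def read_scored_lexicon(path: str | Path) -> dict[str, float]:
    """Tab-separated ``token<TAB>score``."""
    out: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            token, score = line.rstrip("\n").split("\t")[:2]
            out[token.lower()] = float(score)
    return out


def read_subjectivity_lexicon(path: str | Path) -> dict[str, tuple[float, float]]:
    """Tab-separated ``token<TAB>polarity<TAB>strength``."""
    out: dict[str, tuple[float, float]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            token, pol, strength = line.rstrip("\n").split("\t")[:3]
            out[token.lower()] = (float(pol), float(strength))
    return out


def sentiment_scores(seq: TokenSequence, lex: SentimentLexicons) -> np.ndarray:
    """Six slots: [#positive, #negative, sum prior polarity, mean prior
    polarity over matched tokens (0 if none), sum subjectivity polarity,
    sum subjectivity strength]."""
    pos = sum(1 for t in seq.tokens if t in lex.positive_terms)
    neg = sum(1 for t in seq.tokens if t in lex.negative_terms)
    prior = [lex.prior_polarity[t] for t in seq.tokens if t in lex.prior_polarity]
    subj = [lex.subjectivity[t] for t in seq.tokens if t in lex.subjectivity]
    return np.array(
        [
            float(pos),
            float(neg),
            float(sum(prior)),
            float(np.mean(prior)) if prior else 0.0,
            float(sum(p for p, _s in subj)),
            float(sum(s for _p, s in subj)),
        ]
    )


# --------------------------------------------------------------------------
# structural

_SENTENCE_SPLIT = re.compile(r"[.!?]+")
_PUNCT_CHAR = re.compile(r"[^\w\s]")


def structural_features(text: str) -> np.ndarray:
    """Six slots: [word count, character count, sentence count, mean sentence
    length in words, punctuation-character count, uppercase-character ratio].
    Ratios are 0 on empty text."""
    words = _WORD.findall(text.lower())
    sentences = [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]
    sent_lens = [len(_WORD.findall(s.lower())) for s in sentences]
    n_upper = sum(1 for c in text if c.isupper())
    return np.array(
        [
            float(len(words)),
            float(len(text)),
            float(len(sentences)),
            float(np.mean(sent_lens)) if sent_lens else 0.0,
            float(len(_PUNCT_CHAR.findall(text))),
            n_upper / len(text) if text else 0.0,
        ]
    )


# --------------------------------------------------------------------------
# assembly


@dataclass
class FeatureResources:
    """Fitted/loaded resources required to featurize a post."""

    vocabulary: NgramVocabulary
    embeddings: EmbeddingTable
    clusters: ClusterMap
    lexicons: SentimentLexicons

    def block_lengths(self, blocks: Sequence[str] = BLOCK_ORDER) -> dict[str, int]:
        lengths = {
            "ngram": len(self.vocabulary),
            "embedding": self.embeddings.dimension,
            "cluster": self.clusters.n_clusters,
            "sentiment": SENTIMENT_SLOTS,
            "structural": STRUCTURAL_SLOTS,
        }
        return {b: lengths[b] for b in blocks}

    def block_slices(self, blocks: Sequence[str] = BLOCK_ORDER) -> dict[str, slice]:
        slices, offset = {}, 0
        for name, length in self.block_lengths(blocks).items():
            slices[name] = slice(offset, offset + length)
            offset += length
        return slices

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": 1, "resources": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureResources":
        payload = joblib.load(path)
        return payload["resources"]


def _check_blocks(blocks: Sequence[str]) -> tuple[str, ...]:
    ordered = tuple(b for b in BLOCK_ORDER if b in blocks)
    unknown = set(blocks) - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
    if not ordered:
        raise ValueError("at least one feature block must be enabled")
    return ordered


def featurize(
    post: Post | str,
    resources: FeatureResources,
    blocks: Sequence[str] = BLOCK_ORDER,
) -> sp.csr_matrix:
    """One sparse row: the enabled blocks concatenated in canonical order.

    Disabling blocks reproduces ablation layouts; the relative order of the
    remaining blocks never changes.
    """
    text = post.text if isinstance(post, Post) else post
    blocks = _check_blocks(blocks)
    seq = preprocess(text)
    parts: list[sp.csr_matrix] = []
    for name in blocks:
        if name == "ngram":
            parts.append(ngram_vector(seq, resources.vocabulary))
        elif name == "embedding":
            parts.append(sp.csr_matrix(embed_post(seq, resources.embeddings)))
        elif name == "cluster":
            parts.append(sp.csr_matrix(cluster_vector(seq, resources.clusters)))
        elif name == "sentiment":
            parts.append(sp.csr_matrix(sentiment_scores(seq, resources.lexicons)))
        elif name == "structural":
            parts.append(sp.csr_matrix(structural_features(text)))
    return sp.hstack(parts, format="csr")


def featurize_corpus(
    posts: Sequence[Post | str],
    resources: FeatureResources,
    blocks: Sequence[str] = BLOCK_ORDER,
) -> sp.csr_matrix:
    rows = [featurize(p, resources, blocks) for p in posts]
    return sp.vstack(rows, format="csr") if rows else sp.csr_matrix((0, 0))
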
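"""Feature blocks: each against a brute-force or hand-computed oracle, plus
layout and determinism invariants."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pregcohort.features import (
    ClusterMap,
    EmbeddingTable,
    FeatureResources,
    SentimentLexicons,
    TokenSequence,
    cluster_vector,
    embed_post,
    featurize,
    fit_ngram_vocabulary,
    ngram_vector,
    preprocess,
    sentiment_scores,
    structural_features,
)


def seq(*tokens: str) -> TokenSequence:
    return TokenSequence(list(tokens), list(tokens), [""] * len(tokens))


# -- preprocessing ----------------------------------------------------------


def test_preprocess_stems_and_lowercases():
    out = preprocess("Running after BABIES")
    assert out.tokens == ["running", "after", "babies"]
    assert out.stems == ["run", "after", "babi"]


def test_preprocess_keeps_contractions_and_marks_hashtags():
    out = preprocess("I'm loving #BabyShower with @friend!")
    assert "i'm" in out.tokens
    idx = out.tokens.index("babyshower")
    assert out.markers[idx] == "#"
    assert out.markers[out.tokens.index("friend")] == "@"


def test_preprocess_empty_text():
    assert len(preprocess("")) == 0


# -- n-grams ----------------------------------------------------------------


def brute_force_ngram_counts(stems, vocab):
    """Independent enumerator: all 1-3 gram substrings, counted directly."""
    grams = []
    for n in (1, 2, 3):
        grams += [" ".join(stems[i : i + n]) for i in range(len(stems) - n + 1)]
    counts = Counter(g for g in grams if g in vocab.gram_to_index)
    dense = np.zeros(len(vocab))
    for g, c in counts.items():
        dense[vocab.gram_to_index[g]] = c
    return dense


def test_vocabulary_size_on_three_token_document():
    vocab = fit_ngram_vocabulary([seq("i", "am", "pregnant")], min_count=1)
    assert len(vocab) == 6  # 3 unigrams + 2 bigrams + 1 trigram


def test_vocabulary_min_count_filters_and_warns():
    with pytest.warns(UserWarning):
        vocab = fit_ngram_vocabulary([seq("a", "b")], min_count=99)
    assert len(vocab) == 0


def test_vocabulary_set_semantics_and_empty_corpus_error():
    one = fit_ngram_vocabulary([seq("a", "b")], min_count=1)
    two = fit_ngram_vocabulary([seq("a", "b"), seq("a", "b")], min_count=1)
    assert one.gram_to_index == two.gram_to_index
    with pytest.raises(ValueError):
        fit_ngram_vocabulary([], min_count=1)


def test_ngram_vector_counts_and_oov():
    vocab = fit_ngram_vocabulary([seq("baby", "baby")], min_count=1)
    vec = ngram_vector(seq("baby", "baby"), vocab).toarray().ravel()
    assert vec[vocab.gram_to_index["baby"]] == 2
    assert ngram_vector(seq(), vocab).nnz == 0
    assert ngram_vector(seq("zzz"), vocab).nnz == 0


@settings(max_examples=120, deadline=None)
@given(
    st.lists(
        st.sampled_from(["im", "so", "happi", "babi", "week", "pregnant"]),
        min_size=0,
        max_size=12,
    )
)
def test_ngram_vector_matches_brute_force_enumerator(tokens):
    corpus = [seq("im", "so", "happi"), seq("babi", "week", "pregnant", "week")]
    vocab = fit_ngram_vocabulary(corpus + [seq(*tokens)], min_count=1)
    produced = ngram_vector(seq(*tokens), vocab).toarray().ravel()
    expected = brute_force_ngram_counts(list(tokens), vocab)
    assert np.array_equal(produced, expected)


# -- embeddings -------------------------------------------------------------


@pytest.fixture()
def table():
    return EmbeddingTable(
        dimension=3,
        vectors={"baby": np.array([1.0, 2.0, 3.0]), "mom": np.array([0.5, -1.0, 0.0])},
    )


def test_embed_identity_sum_and_oov(table):
    assert np.array_equal(embed_post(seq("baby"), table), [1.0, 2.0, 3.0])
    assert np.array_equal(embed_post(seq("baby", "mom"), table), [1.5, 1.0, 3.0])
    assert np.array_equal(embed_post(seq("zzz"), table), np.zeros(3))


def test_embed_is_additive_over_concatenation(table):
    s1, s2 = seq("baby", "zzz"), seq("mom", "baby")
    concat = seq(*(s1.tokens + s2.tokens))
    assert np.allclose(
        embed_post(concat, table), embed_post(s1, table) + embed_post(s2, table)
    )


def test_embedding_table_rejects_wrong_arity():
    with pytest.raises(ValueError):
        EmbeddingTable(dimension=2, vectors={"x": np.ones(3)})


# -- clusters ---------------------------------------------------------------


def test_cluster_vector_binary_positions():
    cmap = ClusterMap(n_clusters=300, token_to_cluster={"a": 17, "b": 17, "c": 245})
    vec = cluster_vector(seq("a", "b", "c"), cmap)
    assert set(np.flatnonzero(vec)) == {17, 245}
    assert set(np.unique(vec)) <= {0.0, 1.0}
    assert cluster_vector(seq("zzz"), cmap).sum() == 0
    assert cluster_vector(seq("a", "b"), cmap).sum() == 1


# -- sentiment --------------------------------------------------------------


def test_sentiment_scores_counts_and_means():
    lex = SentimentLexicons(
        positive_terms=frozenset({"love"}),
        negative_terms=frozenset({"hate"}),
        prior_polarity={"love": 0.8, "hate": -0.6},
        subjectivity={"love": (1.0, 0.9)},
    )
    block = sentiment_scores(seq("love", "love", "hate"), lex)
    assert block[0] == 2 and block[1] == 1
    assert block[2] == pytest.approx(0.8 + 0.8 - 0.6)
    assert block[3] == pytest.approx((0.8 + 0.8 - 0.6) / 3)
    assert block[4] == pytest.approx(2.0) and block[5] == pytest.approx(1.8)
    assert np.array_equal(sentiment_scores(seq(), lex), np.zeros(6))
    assert np.array_equal(sentiment_scores(seq("zzz"), lex), np.zeros(6))


def test_polar_sets_must_be_disjoint():
    with pytest.raises(ValueError):
        SentimentLexicons(
            positive_terms=frozenset({"x"}), negative_terms=frozenset({"x"})
        )


# -- structural -------------------------------------------------------------


def test_structural_features_hand_counts():
    block = structural_features("Hello world.")
    assert block[0] == 2       # words
    assert block[1] == 12      # characters
    assert block[2] == 1       # sentences
    assert block[3] == 2       # mean sentence length
    assert structural_features("A! B!")[2] == 2
    assert np.array_equal(structural_features(""), np.zeros(6))


# -- assembly ---------------------------------------------------------------


@pytest.fixture()
def resources():
    vocab = fit_ngram_vocabulary([preprocess("im so happy baby")], min_count=1)
    return FeatureResources(
        vocabulary=vocab,
        embeddings=EmbeddingTable(dimension=3, vectors={"baby": np.ones(3)}),
        clusters=ClusterMap(n_clusters=5, token_to_cluster={"baby": 2}),
        lexicons=SentimentLexicons(positive_terms=frozenset({"happy"})),
    )


def test_featurize_layout_and_block_equivalence(resources):
    text = "im so happy baby"
    full = featurize(text, resources).toarray().ravel()
    lengths = resources.block_lengths()
    assert len(full) == sum(lengths.values())
    s = resources.block_slices()
    seq_ = preprocess(text)
    assert np.array_equal(
        full[s["ngram"]], ngram_vector(seq_, resources.vocabulary).toarray().ravel()
    )
    assert np.array_equal(full[s["embedding"]], embed_post(seq_, resources.embeddings))
    assert np.array_equal(full[s["cluster"]], cluster_vector(seq_, resources.clusters))
    assert np.array_equal(full[s["sentiment"]], sentiment_scores(seq_, resources.lexicons))
    assert np.array_equal(full[s["structural"]], structural_features(text))


def test_featurize_ablation_identity_and_unknown_block(resources):
    only = featurize("im so happy", resources, blocks=("ngram",)).toarray().ravel()
    direct = ngram_vector(preprocess("im so happy"), resources.vocabulary)
    assert np.array_equal(only, direct.toarray().ravel())
    with pytest.raises(ValueError):
        featurize("x", resources, blocks=("bogus",))


def test_featurize_deterministic_and_length_invariant(resources):
    a = featurize("im so happy baby", resources).toarray()
    b = featurize("im so happy baby", resources).toarray()
    assert np.array_equal(a, b)
    lengths = {featurize(t, resources).shape[1] for t in ("", "baby", "im so happy")}
    assert len(lengths) == 1
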
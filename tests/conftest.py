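import numpy as np
import pytest

from pregcohort.evaluation import Dataset
from pregcohort.features import featurize_corpus
from pregcohort.patterns import compile_pattern_registry, match_patterns
from pregcohort.synthetic import GeneratorConfig, build_resources, generate_corpus


@pytest.fixture(scope="session")
def registry():
    return compile_pattern_registry()


@pytest.fixture(scope="session")
def corpus_bundle(tmp_path_factory, registry):
    """A medium synthetic corpus, featurized with fixture resources."""
    config = GeneratorConfig(seed=42, n_posts=600, pit_fraction=0.5)
    posts, truth = generate_corpus(config)
    resources = build_resources(
        [p.text for p in posts],
        seed=42,
        out_dir=tmp_path_factory.mktemp("resources"),
        dim=24,
        n_clusters=32,
    )
    pattern_ids = []
    for post in posts:
        match = match_patterns(post, registry)
        pattern_ids.append(match.matched_pattern_ids if match else frozenset())
    dataset = Dataset(
        X=featurize_corpus(posts, resources),
        y=truth["label"].to_numpy(),
        post_ids=list(truth["post_id"]),
        pattern_ids=pattern_ids,
        block_slices=resources.block_slices(),
    )
    return {
        "config": config,
        "posts": posts,
        "truth": truth,
        "resources": resources,
        "dataset": dataset,
    }
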
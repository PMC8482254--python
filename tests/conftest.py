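"""Shared fixtures: one default synthetic world and a classifier trained on
it, built once per session since several modules exercise the same world."""

import pytest

from taglift.corpus_builder import (CommunityGraph, build_labeled_corpus,
                                    expand_seed_communities, split_corpus)
from taglift.geo_prevalence import load_areas
from taglift.synthetic_world import WorldConfig, generate_world
from taglift.text_classifier import train_classifier

WORLD_SEED = 3


@pytest.fixture(scope="session")
def default_world():
    return generate_world(WorldConfig(seed=WORLD_SEED))


@pytest.fixture(scope="session")
def default_split(default_world):
    world = default_world
    graph = CommunityGraph.from_posts(world.posts, world.graph_edges)
    positive = expand_seed_communities(graph, world.config.seed_community, 1000)
    corpus = build_labeled_corpus(world.posts, positive, seed=11)
    return split_corpus(corpus, seed=12)


@pytest.fixture(scope="session")
def trained_model(default_split):
    return train_classifier(default_split.train)


@pytest.fixture(scope="session")
def default_areas(default_world):
    return load_areas(default_world.areas_geojson)


@pytest.fixture
def tiny_world():
    cfg = WorldConfig(
        n_communities=6, n_alcohol_communities=3, posts_per_community=40,
        vocab_background_size=60, vocab_theme_size=12, n_tweets=400,
        n_planted_hashtags=4, n_null_hashtags=20, n_areas=9, seed=5)
    return generate_world(cfg)
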
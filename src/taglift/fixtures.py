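"""Packaged reference lists and small constructors built from them.

``reference_subreddits`` is the 18-community alcohol label source (the seed
community ``drunk`` plus its 17 link neighbors); ``reference_hashtags`` is
the 24-hashtag alcohol list with beverage-category labels used for
category-stratified prevalence runs.
"""

from __future__ import annotations

import json
from importlib import resources

from .corpus_builder import CommunityGraph

SEED_SUBREDDIT = "drunk"


def _data_text(name: str) -> str:
    return resources.files("taglift.data").joinpath(name).read_text("utf-8")


def reference_subreddits() -> list[str]:
    """The 18 alcohol-related community names, seed community last."""
    return [line.strip() for line in
            _data_text("reference_subreddits.txt").splitlines() if line.strip()]


def reference_hashtags() -> dict:
    """The categorized 24-hashtag reference list (raw mapping)."""
    return json.loads(_data_text("reference_hashtags.json"))


def reference_hashtag_set() -> set[str]:
    cats = reference_hashtags()["categories"]
    return {tag for tags in cats.values() for tag in tags}


def reference_category_sets() -> dict[str, set[str]]:
    """Hashtag sets per beverage category, plus the full set under "all"."""
    cats = reference_hashtags()["categories"]
    sets = {name: set(tags) for name, tags in cats.items()}
    sets["all"] = reference_hashtag_set()
    return sets


def reference_community_graph(post_count: int = 1000) -> CommunityGraph:
    """A link graph encoding the reference neighborhood: the seed community
    linked with each of the other 17, every community at ``post_count``
    posts. Directions alternate to exercise both link orientations."""
    names = reference_subreddits()
    others = [n for n in names if n != SEED_SUBREDDIT]
    edges = set()
    for i, name in enumerate(others):
        if i % 2 == 0:
            edges.add((name, SEED_SUBREDDIT))
        else:
            edges.add((SEED_SUBREDDIT, name))
    counts = {name: post_count for name in names}
    return CommunityGraph(post_counts=counts, edges=edges)
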
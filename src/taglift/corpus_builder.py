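"""Weak-labeled training corpus construction from a seed themed community.

The labeling rule is purely structural: every post title from the seed
community and its link-graph neighborhood (communities whose descriptions
link to the seed, or that the seed links to, each holding at least
``min_posts`` posts) is a positive example; an equal number of titles
sampled uniformly without replacement from all remaining communities are
the negatives. The balanced corpus is then shuffled and split
train/validation/test by floor allocation, remainder to test.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ImbalanceError, ParameterError

DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


class Label(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class LabeledExample:
    text: str
    label: Label
    origin: str  # community id


@dataclass
class CommunityGraph:
    """Directed community link graph with per-community post counts.

    An edge (src, dst) means src's description page links to dst. Edge
    endpoints absent from the post table are kept with a zero post count.
    """

    post_counts: dict[str, int]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.edges = set(map(tuple, self.edges))
        for src, dst in self.edges:
            self.post_counts.setdefault(src, 0)
            self.post_counts.setdefault(dst, 0)
        if any(c < 0 for c in self.post_counts.values()):
            raise ParameterError("post counts must be non-negative")

    @classmethod
    def from_posts(cls, posts: list[dict], edges) -> "CommunityGraph":
        counts = Counter(p["community"] for p in posts)
        return cls(post_counts=dict(counts), edges=set(map(tuple, edges)))


@dataclass
class SplitCorpus:
    train: list[LabeledExample]
    validation: list[LabeledExample]
    test: list[LabeledExample]
    fractions: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def expand_seed_communities(graph: CommunityGraph, seed: str,
                            min_posts: int = 1000) -> list[str]:
    """The seed plus its in/out link neighbors with >= ``min_posts`` posts.

    The seed itself is always retained regardless of its post count.
    Returns a sorted list for determinism.
    """
    if seed not in graph.post_counts:
        raise LookupError(f"unknown seed community: {seed!r}")
    neighbors = set()
    for src, dst in graph.edges:
        if dst == seed:
            neighbors.add(src)
        if src == seed:
            neighbors.add(dst)
    neighbors.discard(seed)
    kept = {c for c in neighbors if graph.post_counts.get(c, 0) >= min_posts}
    kept.add(seed)
    return sorted(kept)


def build_labeled_corpus(posts: list[dict], positive_communities,
                         seed: int = 0) -> list[LabeledExample]:
    """Balanced corpus: all positive-community titles + an equal-size
    uniform sample (without replacement) of titles from other communities.

    Titles that are empty after whitespace trimming are dropped from both
    pools. The output order is a deterministic shuffle of the combined set.
    """
    positive_communities = set(positive_communities)
    positives = []
    pool = []
    for p in posts:
        title = p["title"].strip()
        if not title:
            continue
        if p["community"] in positive_communities:
            positives.append(p)
        else:
            pool.append(p)
    n_pos = len(positives)
    if n_pos == 0:
        raise ParameterError("no posts found in the positive communities")
    if len(pool) < n_pos:
        raise ImbalanceError(
            f"negative pool ({len(pool)}) smaller than positives ({n_pos}); "
            "refusing to sample with replacement")
    pool.sort(key=lambda p: p["post_id"])  # canonical order -> seed stability
    positives.sort(key=lambda p: p["post_id"])
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(pool), size=n_pos, replace=False)
    examples = [
        LabeledExample(p["title"].strip(), Label.POSITIVE, p["community"])
        for p in positives
    ] + [
        LabeledExample(pool[i]["title"].strip(), Label.NEGATIVE,
                       pool[i]["community"])
        for i in sorted(map(int, neg_idx))
    ]
    order = rng.permutation(len(examples))
    return [examples[i] for i in order]


def split_corpus(examples, fractions=DEFAULT_FRACTIONS, seed: int = 0
                 ) -> SplitCorpus:
    """Deterministic shuffle then floor allocation; remainder goes to test.

    |train| = floor(f_train * n), |validation| = floor(f_val * n),
    |test| = n - |train| - |validation|.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ParameterError("fractions must be (train, validation, test)")
    if any(f < 0 for f in fractions):
        raise ParameterError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got {sum(fractions)}")
    examples = list(examples)
    n = len(examples)
    # Sort by a canonical key so a permuted input yields the same split.
    keyed = sorted(range(n), key=lambda i: _canonical_key(examples[i]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [examples[keyed[i]] for i in order]
    n_train = math.floor(fractions[0] * n + 1e-9)
    n_val = math.floor(fractions[1] * n + 1e-9)
    return SplitCorpus(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
        fractions=fractions,
    )


def _canonical_key(ex):
    if isinstance(ex, LabeledExample):
        return (ex.origin, ex.text, ex.label.value)
    return (str(ex),)
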
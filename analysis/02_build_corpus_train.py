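#!/usr/bin/env python
"""Expand the seed community's link neighborhood, build the balanced
weak-labeled corpus, split it 0.8/0.1/0.1, and train the classifier.

Writes model.json and a small summary table with the split sizes and
held-out accuracy.
"""

import csv
from pathlib import Path

from taglift import io
from taglift.corpus_builder import (CommunityGraph, build_labeled_corpus,
                                    expand_seed_communities, split_corpus)
from taglift.text_classifier import accuracy, train_classifier

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD = Path(__file__).resolve().parent.parent / "scratch" / "world"
SEED = 20_130_602


def main() -> None:
    posts = io.read_jsonl(WORLD / "posts.jsonl")
    edges = io.read_edge_list(WORLD / "graph.tsv")
    truth = io.read_json(WORLD / "truth.json")

    graph = CommunityGraph.from_posts(posts, edges)
    positive = expand_seed_communities(graph, truth["seed_community"],
                                       min_posts=1000)
    print(f"seed community expands to {len(positive)} positive communities")

    corpus = build_labeled_corpus(posts, positive, seed=SEED)
    split = split_corpus(corpus, (0.8, 0.1, 0.1), seed=SEED + 1)
    print(f"balanced corpus: {len(corpus)} examples -> "
          f"{len(split.train)}/{len(split.validation)}/{len(split.test)}")

    model = train_classifier(split.train)
    model.save(RESULTS / "model.json")
    acc_val = accuracy(model, split.validation)
    acc_test = accuracy(model, split.test)
    print(f"validation accuracy {acc_val:.3f}, test accuracy {acc_test:.3f}")

    with (RESULTS / "corpus_summary.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["positive_communities", "corpus_size", "train",
                    "validation", "test", "val_accuracy", "test_accuracy"])
        w.writerow([len(positive), len(corpus), len(split.train),
                    len(split.validation), len(split.test),
                    round(acc_val, 4), round(acc_test, 4)])


if __name__ == "__main__":
    main()
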
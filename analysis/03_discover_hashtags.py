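#!/usr/bin/env python
"""Screen every hashtag for enrichment among classifier-positive tweets
(one-tailed chi-square, >=5 occurrences, Benjamini-Hochberg FDR 0.05) and
compare the selected set against the planted truth.
"""

from pathlib import Path

from taglift import io
from taglift.hashtag_discovery import discover, results_to_json
from taglift.text_classifier import ClassifierModel

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD = Path(__file__).resolve().parent.parent / "scratch" / "world"


def main() -> None:
    tweets = io.read_jsonl(WORLD / "tweets.jsonl")
    truth = io.read_json(WORLD / "truth.json")
    model = ClassifierModel.load(RESULTS / "model.json")

    result = discover(tweets, model, q=0.05, min_count=5)
    io.write_json(results_to_json(result), RESULTS / "hashtags.json")

    planted = set(truth["planted_hashtags"])
    selected = set(result.significant)
    sensitivity = len(selected & planted) / len(planted)
    fdr = len(selected - planted) / max(1, len(selected))
    print(f"{result.n_positive_calls} positive / {result.n_negative_calls} "
          f"negative calls over {result.n_input} tweets")
    print(f"tested {len(result.results)} hashtags "
          f"({result.n_below_min_count} below min count)")
    print(f"selected {len(selected)}: sensitivity {sensitivity:.2f}, "
          f"empirical FDR {fdr:.2f}")
    print("significant:", ", ".join(result.significant))


if __name__ == "__main__":
    main()
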
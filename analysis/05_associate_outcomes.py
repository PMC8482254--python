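#!/usr/bin/env python
"""Associate per-area prevalence with the generated outcomes: crude
Spearman correlation and confounder-adjusted OLS, one row per outcome and
hashtag subset. The planted outcome should show a strong positive
association; the independent outcome should not.
"""

from pathlib import Path

from taglift import io
from taglift.association import results_to_frame, run_suite
from taglift.geo_prevalence import load_areas

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD = Path(__file__).resolve().parent.parent / "scratch" / "world"


def main() -> None:
    tweets = io.read_jsonl(WORLD / "tweets.jsonl")
    areas = load_areas(WORLD / "areas.geojson")
    truth = io.read_json(WORLD / "truth.json")
    significant = {r["hashtag"] for r in io.read_json(RESULTS / "hashtags.json")
                   if r["significant"]}

    sets = {"all": significant,
            "planted_first5": set(truth["planted_hashtags"][:5]) & significant}
    results = run_suite(tweets, areas, sets, year_range=(2013, 2018),
                        min_tweets=1, min_population=1000)
    frame = results_to_frame(results)
    frame.to_csv(RESULTS / "association.csv", index=False)

    print(frame.to_string(index=False,
                          float_format=lambda v: f"{v:.4g}"))
    linked = frame[(frame.outcome == "alcohol_outcome")
                   & (frame.category == "all")].iloc[0]
    print(f"\nplanted outcome: rho={linked.spearman_rho:.3f} "
          f"(p={linked.spearman_p:.2g}), adjusted beta={linked.beta:.3f} "
          f"(p={linked.beta_p:.2g}); generator true_beta="
          f"{truth['true_beta']} (beta is attenuated toward 0 by "
          f"classification and hashtag noise in the measured prevalence)")


if __name__ == "__main__":
    main()
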
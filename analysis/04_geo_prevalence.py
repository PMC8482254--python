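#!/usr/bin/env python
"""Filter tweets to those carrying a significant hashtag, map geotags to
areas, and compute per-10,000-person prevalence with the inclusion filters
(>=1 tweet, mean population strictly > 1000).
"""

import csv
from pathlib import Path

from taglift import io
from taglift.geo_prevalence import (apply_inclusion_filters, compute_prevalence,
                                    filter_alcohol_tweets, load_areas)

RESULTS = Path(__file__).resolve().parent.parent / "results"
WORLD = Path(__file__).resolve().parent.parent / "scratch" / "world"


def main() -> None:
    tweets = io.read_jsonl(WORLD / "tweets.jsonl")
    areas = load_areas(WORLD / "areas.geojson")
    significant = {r["hashtag"] for r in io.read_json(RESULTS / "hashtags.json")
                   if r["significant"]}

    alcohol, geotagged = filter_alcohol_tweets(tweets, significant)
    report = compute_prevalence(geotagged, areas, year_range=(2013, 2018))
    included = apply_inclusion_filters(report.records, min_tweets=1,
                                       min_population=1000)

    with (RESULTS / "prevalence.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["area_id", "level", "tweet_count", "mean_population",
                    "per_10k"])
        for r in report.records:
            w.writerow([r.area_id, r.level, r.tweet_count,
                        round(r.mean_population, 2), round(r.per_10k, 4)])

    print(f"funnel: {len(tweets)} tweets -> {len(alcohol)} alcohol-tagged "
          f"-> {len(geotagged)} geotagged -> {report.assigned_total} assigned "
          f"({len(report.unassigned)} unassigned)")
    print(f"{len(included)} of {len(report.records)} areas pass the "
          f"inclusion filters")
    top = sorted(report.records, key=lambda r: -r.per_10k)[:3]
    for r in top:
        print(f"  highest prevalence: {r.area_id} {r.per_10k:.1f} per 10k "
              f"({r.tweet_count} tweets, pop {r.mean_population:.0f})")


if __name__ == "__main__":
    main()
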
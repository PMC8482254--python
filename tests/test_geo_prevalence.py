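"""Point-in-area assignment, per-capita prevalence, and inclusion filters."""

import pytest

from taglift.errors import GeometryError
from taglift.geo_prevalence import (apply_inclusion_filters, assign_area,
                                    compute_prevalence, filter_alcohol_tweets,
                                    load_areas)


def _square(area_id, x0=0.0, y0=0.0, size=1.0, pop=None, outcomes=None):
    ring = [[x0, y0], [x0 + size, y0], [x0 + size, y0 + size],
            [x0, y0 + size], [x0, y0]]
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": {
            "area_id": area_id, "level": "county",
            "population": pop or {"2017": 10000, "2018": 10000},
            "confounders": {k: 0.0 for k in (
                "pct_white", "pct_black", "pct_hispanic", "median_income",
                "pct_hs", "pct_bachelor", "males_per_100_females")},
            "outcomes": outcomes or {},
        },
    }


def _areas(*features):
    return load_areas({"type": "FeatureCollection", "features": list(features)})


# ---- assign_area -------------------------------------------------------

def test_interior_point_inside():
    areas = _areas(_square("a"))
    assert assign_area((0.5, 0.5), areas) == "a"


def test_exterior_point_none():
    areas = _areas(_square("a"))
    assert assign_area((2.0, 2.0), areas) is None


def test_boundary_point_inside_and_overlap_tie_break():
    areas = _areas(_square("b"), _square("a"))  # identical overlapping squares
    assert assign_area((0.0, 0.5), areas) == "a"  # edge counts as inside
    assert assign_area((0.5, 0.5), areas) == "a"  # smaller id wins


def test_invalid_polygon_rejected_at_load():
    bowtie = {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [[
            [0, 0], [1, 1], [1, 0], [0, 1], [0, 0]]]},
        "properties": _square("bad")["properties"],
    }
    with pytest.raises(GeometryError):
        _areas(bowtie)


# ---- filter_alcohol_tweets ---------------------------------------------

def test_filter_on_hashtag_intersection():
    tweets = [
        {"tweet_id": "1", "text": "", "hashtags": ["beer", "cats"],
         "lat": 0.5, "lon": 0.5},
        {"tweet_id": "2", "text": "", "hashtags": ["cats"]},
        {"tweet_id": "3", "text": "", "hashtags": ["beer"]},  # no geotag
    ]
    kept, geotagged = filter_alcohol_tweets(tweets, {"beer"})
    assert [t["tweet_id"] for t in kept] == ["1", "3"]
    assert [t["tweet_id"] for t in geotagged] == ["1"]


def test_category_restriction_subsets(default_world):
    planted = default_world.truth.planted_hashtags
    all_kept, _ = filter_alcohol_tweets(default_world.tweets, set(planted))
    sub_kept, _ = filter_alcohol_tweets(default_world.tweets, set(planted[:5]))
    sub_ids = {t["tweet_id"] for t in sub_kept}
    assert sub_ids <= {t["tweet_id"] for t in all_kept}
    assert all(set(t["hashtags"]) & set(planted[:5]) for t in sub_kept)


# ---- compute_prevalence ------------------------------------------------

def test_prevalence_arithmetic():
    areas = _areas(_square("a", pop={"2017": 9000, "2018": 11000}))
    tweets = [{"tweet_id": str(i), "text": "", "hashtags": ["x"],
               "lat": 0.5, "lon": 0.5} for i in range(5)]
    report = compute_prevalence(tweets, areas, year_range=(2017, 2018))
    rec = report.records[0]
    assert rec.mean_population == 10000
    assert rec.per_10k == pytest.approx(5.0)


def test_zero_tweets_zero_prevalence():
    areas = _areas(_square("a"))
    report = compute_prevalence([], areas, year_range=(2017, 2018))
    assert report.records[0].tweet_count == 0
    assert report.records[0].per_10k == 0.0


def test_conservation_assigned_plus_unassigned(default_world, default_areas):
    geo = [t for t in default_world.tweets if "lat" in t]
    report = compute_prevalence(geo, default_areas)
    assert report.assigned_total + len(report.unassigned) == len(geo)


def test_prevalence_matches_generator_allocation(default_world, default_areas):
    geo = [t for t in default_world.tweets if "lat" in t]
    report = compute_prevalence(geo, default_areas)
    truth = default_world.truth.area_geotagged_counts
    assert {r.area_id: r.tweet_count for r in report.records} == truth
    assert not report.unassigned


def test_scale_equivariance():
    """Multiplying every population by k divides every per_10k by k."""
    tweets = [{"tweet_id": str(i), "text": "", "hashtags": ["x"],
               "lat": 0.5, "lon": 0.5} for i in range(7)]
    base = _areas(_square("a", pop={"2017": 5000}))
    scaled = _areas(_square("a", pop={"2017": 15000}))
    r1 = compute_prevalence(tweets, base, year_range=(2017, 2017)).records[0]
    r2 = compute_prevalence(tweets, scaled, year_range=(2017, 2017)).records[0]
    assert r1.per_10k == pytest.approx(3 * r2.per_10k)


def test_zero_population_area_flagged():
    areas = _areas(_square("a", pop={"2017": 0}), _square("b", x0=2.0))
    report = compute_prevalence([], areas, year_range=(2017, 2017))
    assert report.excluded_areas == ["a"]
    assert [r.area_id for r in report.records] == ["b"]


# ---- apply_inclusion_filters -------------------------------------------

def _record(area_id, count, pop):
    from taglift.geo_prevalence import PrevalenceRecord
    return PrevalenceRecord(area_id, "county", count, pop,
                            count / pop * 10000 if pop else 0.0)


def test_inclusion_filters_boundaries():
    records = [
        _record("zero_tweets", 0, 5000),
        _record("boundary_pop", 3, 1000.0),  # strict >: excluded
        _record("ok", 1, 1000.5),
    ]
    kept = apply_inclusion_filters(records, min_tweets=1, min_population=1000)
    assert [r.area_id for r in kept] == ["ok"]


def test_inclusion_noop_configuration():
    records = [_record("a", 0, 1.0), _record("b", 9, 2.0)]
    assert apply_inclusion_filters(records, min_tweets=0,
                                   min_population=0) == records
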
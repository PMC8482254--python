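"""Geotagged-post area assignment and population-normalized prevalence.

Areas come from a GeoJSON FeatureCollection whose feature properties carry
an area_id, a geographic level, yearly populations, the seven area
confounders, and named outcome measures. Point-in-polygon containment is
boundary-inclusive; a point claimed by several areas goes to the
lexicographically smallest area_id. Prevalence is the area's tweet count
divided by its mean population over the configured year range, scaled per
10,000 persons by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point, shape
from shapely.strtree import STRtree

from . import io
from .errors import GeometryError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 10_000.0
DEFAULT_YEAR_RANGE = (2013, 2018)

CONFOUNDER_FIELDS = (
    "pct_white",
    "pct_black",
    "pct_hispanic",
    "median_income",
    "pct_hs",
    "pct_bachelor",
    "males_per_100_females",
)


@dataclass
class GeoArea:
    area_id: str
    level: str
    geometry: "shapely.Geometry"
    population_by_year: dict[int, float]
    confounders: dict[str, float]
    outcomes: dict[str, float]

    def mean_population(self, year_range=DEFAULT_YEAR_RANGE) -> float:
        """Arithmetic mean of the population estimates whose year falls in
        [year_range[0], year_range[1]]."""
        lo, hi = year_range
        vals = [v for y, v in self.population_by_year.items() if lo <= y <= hi]
        if not vals:
            raise ParameterError(
                f"area {self.area_id}: no population years in {year_range}")
        return float(np.mean(vals))


@dataclass(frozen=True)
class PrevalenceRecord:
    area_id: str
    level: str
    tweet_count: int
    mean_population: float
    per_10k: float


@dataclass
class PrevalenceReport:
    records: list[PrevalenceRecord]
    unassigned: list[tuple[float, float]]  # (lon, lat) of unmapped geotags
    excluded_areas: list[str]  # zero mean population -> prevalence undefined

    @property
    def assigned_total(self) -> int:
        return sum(r.tweet_count for r in self.records)


def load_areas(source) -> list[GeoArea]:
    """Parse a FeatureCollection (path or mapping) into GeoArea objects.

    Invalid polygons raise at load time so queries never hit bad geometry.
    """
    obj = io.read_json(source) if not isinstance(source, dict) else source
    if obj.get("type") != "FeatureCollection":
        raise GeometryError("expected a GeoJSON FeatureCollection")
    areas = []
    for feat in obj.get("features", []):
        props = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise GeometryError(
                f"invalid polygon for area {props.get('area_id')!r}")
        missing = [f for f in CONFOUNDER_FIELDS
                   if f not in props.get("confounders", {})]
        if missing:
            raise ParameterError(
                f"area {props.get('area_id')!r} missing confounders: {missing}")
        if any(v < 0 for v in props.get("population", {}).values()):
            raise ParameterError(
                f"area {props.get('area_id')!r} has a negative population")
        areas.append(GeoArea(
            area_id=str(props["area_id"]),
            level=str(props.get("level", "county")),
            geometry=geom,
            population_by_year={int(y): float(v)
                                for y, v in props.get("population", {}).items()},
            confounders={k: float(v)
                         for k, v in props.get("confounders", {}).items()},
            outcomes={k: float(v) for k, v in props.get("outcomes", {}).items()},
        ))
    return areas


def assign_area(point: tuple[float, float], areas: list[GeoArea]) -> str | None:
    """Area containing (lon, lat); boundary points are inside; overlapping
    claims resolve to the smallest area_id; None when outside all areas."""
    pt = Point(point[0], point[1])
    claims = [a.area_id for a in areas if a.geometry.covers(pt)]
    return min(claims) if claims else None


def assign_points(lons, lats, areas: list[GeoArea]) -> list[str | None]:
    """Vectorized assign_area over many points (STRtree candidate lookup)."""
    geoms = [a.geometry for a in areas]
    ids = [a.area_id for a in areas]
    tree = STRtree(geoms)
    pts = shapely.points(np.asarray(lons, dtype=float),
                         np.asarray(lats, dtype=float))
    out: list[str | None] = [None] * len(pts)
    pt_idx, geom_idx = tree.query(pts, predicate="intersects")
    for p, g in zip(pt_idx, geom_idx):
        aid = ids[int(g)]
        if out[int(p)] is None or aid < out[int(p)]:
            out[int(p)] = aid
    return out


def is_geotagged(tweet: dict) -> bool:
    return tweet.get("lat") is not None and tweet.get("lon") is not None


def filter_alcohol_tweets(tweets: list[dict], significant_hashtags
                          ) -> tuple[list[dict], list[dict]]:
    """Tweets whose hashtag set intersects the significant set, and the
    geotagged subset of those. Hashtags are lowercase, '#'-stripped."""
    from .hashtag_discovery import tweet_hashtags

    sig = {str(t).casefold().lstrip("#") for t in significant_hashtags}
    kept = [tw for tw in tweets if tweet_hashtags(tw) & sig]
    geotagged = [tw for tw in kept if is_geotagged(tw)]
    return kept, geotagged


def compute_prevalence(tweets: list[dict], areas: list[GeoArea],
                       year_range=DEFAULT_YEAR_RANGE,
                       scale: float = DEFAULT_SCALE) -> PrevalenceReport:
    """Per-area tweet counts and per-capita prevalence.

    Only geotagged tweets are counted. Tweets falling outside every area are
    reported in the ``unassigned`` list, never silently dropped; every area
    gets a record, including zero-count ones. Areas whose mean population is
    zero have undefined prevalence and are excluded (flagged).
    """
    geo = [tw for tw in tweets if is_geotagged(tw)]
    counts = {a.area_id: 0 for a in areas}
    unassigned: list[tuple[float, float]] = []
    if geo:
        assigned = assign_points([tw["lon"] for tw in geo],
                                 [tw["lat"] for tw in geo], areas)
        for tw, aid in zip(geo, assigned):
            if aid is None:
                unassigned.append((float(tw["lon"]), float(tw["lat"])))
            else:
                counts[aid] += 1
    if unassigned:
        logger.info("%d geotagged tweets fell outside every area",
                    len(unassigned))
    records = []
    excluded = []
    for area in areas:
        mean_pop = area.mean_population(year_range)
        if mean_pop == 0:
            excluded.append(area.area_id)
            logger.warning("area %s has zero mean population; prevalence "
                           "undefined", area.area_id)
            continue
        n = counts[area.area_id]
        records.append(PrevalenceRecord(
            area_id=area.area_id, level=area.level, tweet_count=n,
            mean_population=mean_pop, per_10k=n / mean_pop * scale))
    return PrevalenceReport(records=records, unassigned=unassigned,
                            excluded_areas=excluded)


def apply_inclusion_filters(records: list[PrevalenceRecord],
                            min_tweets: int = 1,
                            min_population: float = 1000.0
                            ) -> list[PrevalenceRecord]:
    """Keep areas with tweet_count >= min_tweets and mean population
    strictly greater than min_population."""
    return [r for r in records
            if r.tweet_count >= min_tweets and r.mean_population > min_population]
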
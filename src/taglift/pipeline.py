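"""End-to-end orchestration with one global seed and a run manifest.

Stage order: simulate (optional) -> expand seed neighborhood -> build the
balanced weak-labeled corpus -> split -> train the classifier -> hashtag
enrichment discovery -> alcohol-tweet filtering and area prevalence ->
crude + adjusted association. Every stage draws its seed by hashing
(global seed, stage name), so partial reruns reproduce stage-for-stage.
All thresholds live in PipelineConfig; the defaults are the reference
analysis settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io
from ._seeds import derive_seed
from .association import results_to_frame, run_suite
from .corpus_builder import (DEFAULT_FRACTIONS, CommunityGraph,
                             build_labeled_corpus, expand_seed_communities,
                             split_corpus)
from .errors import ConfigurationError
from .geo_prevalence import (apply_inclusion_filters, compute_prevalence,
                             filter_alcohol_tweets, is_geotagged, load_areas)
from .hashtag_discovery import discover, results_to_json
from .synthetic_world import WorldConfig, generate_world, write_world
from .text_classifier import TrainConfig, train_classifier

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults match the reference analysis settings
    (min_posts=1000, 0.8/0.1/0.1 split, 0.5 call threshold, FDR 0.05,
    min_count 5, per-10,000 scaling, county filters >=1 tweet and
    population strictly > 1000, years 2013-2018)."""

    seed: int = 0
    min_posts: int = 1000
    split_fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    threshold: float = 0.5
    fdr: float = 0.05
    min_count: int = 5
    scale: float = 10_000.0
    min_tweets: int = 1
    min_population: float = 1000.0
    year_range: tuple[int, int] = (2013, 2018)
    l2_strength: float = 1.0
    seed_community: str | None = None  # default: the world's seed community
    categories: dict[str, set] | None = None  # extra hashtag subsets
    world: WorldConfig | None = None  # used with simulate=True
    posts_path: str | None = None
    graph_path: str | None = None
    tweets_path: str | None = None
    areas_path: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.categories is not None:
            d["categories"] = {k: sorted(v) for k, v in self.categories.items()}
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    association: "object"  # pandas DataFrame


def _echo_overrides(config: PipelineConfig) -> None:
    defaults = PipelineConfig()
    for f in dataclasses.fields(PipelineConfig):
        if f.name in {"seed", "world", "posts_path", "graph_path",
                      "tweets_path", "areas_path", "seed_community",
                      "categories"}:
            continue
        if getattr(config, f.name) != getattr(defaults, f.name):
            logger.info("override: %s=%r (default %r)", f.name,
                        getattr(config, f.name), getattr(defaults, f.name))


def run_all(config: PipelineConfig, out_dir, simulate: bool = False
            ) -> PipelineResult:
    """Run every stage; write all artifacts plus manifest.json to out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _echo_overrides(config)

    if simulate:
        world_cfg = config.world or WorldConfig()
        world_cfg = dataclasses.replace(
            world_cfg, seed=derive_seed(config.seed, "simulate"))
        world = generate_world(world_cfg)
        write_world(world, out_dir / "world")
        posts, edges = world.posts, world.graph_edges
        tweets = world.tweets
        areas = load_areas(world.areas_geojson)
        seed_community = config.seed_community or world_cfg.seed_community
    else:
        for name in ("posts_path", "graph_path", "tweets_path", "areas_path"):
            if getattr(config, name) is None:
                raise ConfigurationError(
                    f"{name} is required when simulate=False")
        posts = io.read_jsonl(config.posts_path)
        edges = io.read_edge_list(config.graph_path)
        tweets = io.read_jsonl(config.tweets_path)
        areas = load_areas(config.areas_path)
        if config.seed_community is None:
            raise ConfigurationError(
                "seed_community is required when simulate=False")
        seed_community = config.seed_community

    graph = CommunityGraph.from_posts(posts, edges)
    positive = expand_seed_communities(graph, seed_community, config.min_posts)
    corpus = build_labeled_corpus(posts, positive,
                                  seed=derive_seed(config.seed, "corpus"))
    split = split_corpus(corpus, config.split_fractions,
                         seed=derive_seed(config.seed, "split"))
    io.write_jsonl(
        [{"text": ex.text, "label": ex.label.value, "origin": ex.origin}
         for ex in corpus], out_dir / "corpus.jsonl")

    model = train_classifier(split.train, TrainConfig(
        l2_strength=config.l2_strength, seed=derive_seed(config.seed, "train")))
    model.save(out_dir / "model.json")

    discovery = discover(tweets, model, q=config.fdr,
                         min_count=config.min_count,
                         threshold=config.threshold)
    io.write_json(results_to_json(discovery), out_dir / "hashtags.json")
    significant = set(discovery.significant)

    alcohol, geotagged_alcohol = filter_alcohol_tweets(tweets, significant)
    report = compute_prevalence(geotagged_alcohol, areas, config.year_range,
                                config.scale)
    included = apply_inclusion_filters(report.records, config.min_tweets,
                                       config.min_population)
    prev_rows = [
        {"area_id": r.area_id, "level": r.level, "tweet_count": r.tweet_count,
         "mean_population": r.mean_population, "per_10k": r.per_10k}
        for r in report.records
    ]
    _write_csv(prev_rows, out_dir / "prevalence.csv")

    hashtag_sets = {"all": significant}
    if config.categories:
        for name, tags in config.categories.items():
            hashtag_sets[name] = set(tags) & significant
    assoc = run_suite(tweets, areas, hashtag_sets,
                      year_range=config.year_range,
                      min_tweets=config.min_tweets,
                      min_population=config.min_population,
                      scale=config.scale)
    frame = results_to_frame(assoc)
    frame.to_csv(out_dir / "association.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package": "taglift 0.1.0",
        "counts": {
            "posts": len(posts),
            "positive_communities": len(positive),
            "corpus_examples": len(corpus),
            "train": len(split.train),
            "validation": len(split.validation),
            "test": len(split.test),
            "tweets": len(tweets),
            "tweets_with_hashtags": len(tweets) - discovery.n_dropped_no_hashtag,
            "hashtags_tested": len(discovery.results),
            "hashtags_significant": len(significant),
            "alcohol_tweets": len(alcohol),
            "geotagged_alcohol_tweets": len(geotagged_alcohol),
            "area_assigned_tweets": report.assigned_total,
            "unassigned_tweets": len(report.unassigned),
            "areas": len(areas),
            "areas_included": len(included),
            "association_rows": len(frame),
        },
    }
    io.write_json(manifest, out_dir / "manifest.json")
    return PipelineResult(out_dir=out_dir, manifest=manifest, association=frame)


def _write_csv(rows: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)
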
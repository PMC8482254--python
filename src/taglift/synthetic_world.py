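"""Synthetic social-media world with planted, recoverable ground truth.

The generator emulates the data regime the pipeline is built for:

* **Community posts** (Reddit-like): a fixed set of themed ("alcohol")
  communities and background communities. Every post title is a bag of
  1 + Poisson(8) tokens drawn from a two-component mixture — in themed
  communities each token comes from a small theme lexicon with probability
  ``theme_token_rate``, otherwise from a large background lexicon; background
  communities leak theme tokens at the much smaller ``leak_token_rate``.
* **Link graph**: the seed community is linked (in one direction or the
  other) to every other themed community and to no background community,
  so neighborhood expansion from the seed recovers exactly the themed set.
* **Tweets** (Twitter-like): each tweet carries a latent theme indicator
  z ~ Bernoulli(``latent_theme_rate``); its text tokens use the same mixture
  keyed by z, and each of its 1 + Poisson(0.5) hashtags is drawn from the
  planted hashtag set with probability ``planted_rate_pos`` (z=1) or
  ``planted_rate_neg`` (z=0), else uniformly from the null hashtag set.
* **Geography**: areas are unit grid cells with log-normal populations
  (jittered ±5% per year). Tweets are assigned to areas with probability
  proportional to population; geotags fall uniformly inside the assigned
  cell. The area outcome is linear-Gaussian in the area's per-10k latent
  tweet prevalence plus seven standard-normal confounders, with known
  coefficient ``true_beta`` — so downstream hashtag discovery and the
  adjusted regression both have an exactly known target.

Everything is a pure function of (config, seed). One RNG stream per
sub-generator (posts, tweets, geography) keyed by hashing (seed, name),
so changing tweet counts never perturbs the geography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import io
from ._seeds import stream_rng
from .errors import ParameterError

PREVALENCE_SCALE = 10_000.0

CONFOUNDER_FIELDS = (
    "pct_white",
    "pct_black",
    "pct_hispanic",
    "median_income",
    "pct_hs",
    "pct_bachelor",
    "males_per_100_females",
)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the data-generating process.

    Defaults define the reference study conditions: 18 themed communities
    among 40 (each with enough posts to clear the 1000-post expansion rule),
    20,000 tweets with a 10% latent theme rate, 15 planted vs 185 null
    hashtags at per-hashtag-draw rates q1=0.6 / q0=0.02, and 100 grid-cell
    areas over the 2013-2018 population years.
    """

    n_communities: int = 40
    n_alcohol_communities: int = 18
    posts_per_community: int = 1200
    vocab_background_size: int = 500
    vocab_theme_size: int = 50
    theme_token_rate: float = 0.3
    leak_token_rate: float = 0.02
    n_tweets: int = 20_000
    latent_theme_rate: float = 0.1
    n_planted_hashtags: int = 15
    n_null_hashtags: int = 185
    planted_rate_pos: float = 0.6  # q1
    planted_rate_neg: float = 0.02  # q0
    geotag_rate: float = 1.0
    n_areas: int = 100
    years: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017, 2018)
    true_beta: float = 2.0
    intercept: float = 10.0
    confounder_effects: tuple[float, ...] = (0.5, -0.3, 0.2, 0.4, -0.2, 0.3, 0.1)
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "theme_token_rate": self.theme_token_rate,
            "leak_token_rate": self.leak_token_rate,
            "latent_theme_rate": self.latent_theme_rate,
            "planted_rate_pos": self.planted_rate_pos,
            "planted_rate_neg": self.planted_rate_neg,
            "geotag_rate": self.geotag_rate,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name}={p} is not a probability")
        counts = {
            "n_communities": self.n_communities,
            "n_alcohol_communities": self.n_alcohol_communities,
            "posts_per_community": self.posts_per_community,
            "vocab_background_size": self.vocab_background_size,
            "vocab_theme_size": self.vocab_theme_size,
            "n_tweets": self.n_tweets,
            "n_planted_hashtags": self.n_planted_hashtags,
            "n_null_hashtags": self.n_null_hashtags,
            "n_areas": self.n_areas,
        }
        for name, c in counts.items():
            if int(c) != c or c <= 0:
                raise ParameterError(f"{name}={c} must be a positive integer")
        if self.n_alcohol_communities >= self.n_communities:
            raise ParameterError(
                "n_alcohol_communities must be smaller than n_communities"
            )
        if len(self.confounder_effects) != len(CONFOUNDER_FIELDS):
            raise ParameterError(
                f"confounder_effects needs {len(CONFOUNDER_FIELDS)} entries"
            )
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if not self.years:
            raise ParameterError("years must be non-empty")

    # ---- derived naming -------------------------------------------------
    @property
    def theme_communities(self) -> list[str]:
        return [f"alc{i:02d}" for i in range(self.n_alcohol_communities)]

    @property
    def background_communities(self) -> list[str]:
        n_bg = self.n_communities - self.n_alcohol_communities
        return [f"bg{i:02d}" for i in range(n_bg)]

    @property
    def seed_community(self) -> str:
        return self.theme_communities[0]

    @property
    def planted_hashtags(self) -> list[str]:
        return [f"ptag{i:02d}" for i in range(self.n_planted_hashtags)]

    @property
    def null_hashtags(self) -> list[str]:
        return [f"ntag{i:03d}" for i in range(self.n_null_hashtags)]


@dataclass
class WorldTruth:
    """Planted ground truth recorded alongside the generated corpora."""

    planted_hashtags: list[str]
    true_beta: float
    area_latent_rate: dict[str, float]  # fraction of an area's tweets with z=1
    area_latent_per10k: dict[str, float]  # geotagged z=1 tweets per 10k persons
    area_geotagged_counts: dict[str, int]
    theme_communities: list[str]
    seed_community: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class World:
    config: WorldConfig
    posts: list[dict]
    graph_edges: list[tuple[str, str]]
    tweets: list[dict]
    areas_geojson: dict
    truth: WorldTruth


def _mixture_tokens(rng, n_docs, theme_rate_per_doc, theme_vocab, bg_vocab,
                    mean_extra_tokens=8.0):
    """Token strings per document from the two-component lexicon mixture."""
    lengths = 1 + rng.poisson(mean_extra_tokens, n_docs)
    total = int(lengths.sum())
    per_token_rate = np.repeat(np.asarray(theme_rate_per_doc, dtype=float), lengths)
    is_theme = rng.random(total) < per_token_rate
    theme_idx = rng.integers(0, len(theme_vocab), total)
    bg_idx = rng.integers(0, len(bg_vocab), total)
    flat = np.where(is_theme, theme_vocab[theme_idx], bg_vocab[bg_idx])
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    return [" ".join(flat[bounds[i]:bounds[i + 1]]) for i in range(n_docs)]


def _generate_posts(cfg: WorldConfig, rng) -> tuple[list[dict], list[tuple[str, str]]]:
    theme_vocab = np.array([f"themeword{i:03d}" for i in range(cfg.vocab_theme_size)],
                           dtype=object)
    bg_vocab = np.array([f"word{i:04d}" for i in range(cfg.vocab_background_size)],
                        dtype=object)
    communities = cfg.theme_communities + cfg.background_communities
    rates = np.concatenate([
        np.full(cfg.n_alcohol_communities, cfg.theme_token_rate),
        np.full(cfg.n_communities - cfg.n_alcohol_communities, cfg.leak_token_rate),
    ])
    per_doc_rate = np.repeat(rates, cfg.posts_per_community)
    comm_of_post = np.repeat(np.array(communities, dtype=object),
                             cfg.posts_per_community)
    n_posts = cfg.n_communities * cfg.posts_per_community
    titles = _mixture_tokens(rng, n_posts, per_doc_rate, theme_vocab, bg_vocab)
    posts = [
        {"post_id": f"p{i:06d}", "community": str(comm_of_post[i]),
         "title": titles[i]}
        for i in range(n_posts)
    ]

    # Seed community links to every other theme community, direction random;
    # a few background<->background edges keep the graph nontrivial.
    seed_comm = cfg.seed_community
    edges: list[tuple[str, str]] = []
    for comm in cfg.theme_communities[1:]:
        if rng.random() < 0.5:
            edges.append((seed_comm, comm))
        else:
            edges.append((comm, seed_comm))
    bg = cfg.background_communities
    if len(bg) >= 2:
        n_extra = min(5, len(bg) - 1)
        for _ in range(n_extra):
            i, j = rng.choice(len(bg), size=2, replace=False)
            edges.append((bg[int(i)], bg[int(j)]))
    return posts, edges


def _generate_tweets(cfg: WorldConfig, rng) -> tuple[list[dict], np.ndarray]:
    theme_vocab = np.array([f"themeword{i:03d}" for i in range(cfg.vocab_theme_size)],
                           dtype=object)
    bg_vocab = np.array([f"word{i:04d}" for i in range(cfg.vocab_background_size)],
                        dtype=object)
    planted = np.array(cfg.planted_hashtags, dtype=object)
    null = np.array(cfg.null_hashtags, dtype=object)

    n = cfg.n_tweets
    z = rng.random(n) < cfg.latent_theme_rate
    texts = _mixture_tokens(
        rng, n, np.where(z, cfg.theme_token_rate, cfg.leak_token_rate),
        theme_vocab, bg_vocab)

    n_tags = 1 + rng.poisson(0.5, n)
    total_tags = int(n_tags.sum())
    tag_rate = np.repeat(np.where(z, cfg.planted_rate_pos, cfg.planted_rate_neg),
                         n_tags)
    from_planted = rng.random(total_tags) < tag_rate
    p_idx = rng.integers(0, len(planted), total_tags)
    n_idx = rng.integers(0, len(null), total_tags)
    flat_tags = np.where(from_planted, planted[p_idx], null[n_idx])
    bounds = np.concatenate([[0], np.cumsum(n_tags)])

    years = np.array(cfg.years)
    year_of = years[rng.integers(0, len(years), n)]

    tweets = []
    for i in range(n):
        tags = [str(t) for t in flat_tags[bounds[i]:bounds[i + 1]]]
        text = texts[i] + " " + " ".join("#" + t for t in tags)
        tweets.append({
            "tweet_id": f"t{i:06d}",
            "text": text,
            "hashtags": tags,
            "year": int(year_of[i]),
        })
    return tweets, z


def _cell_bounds(idx: int, side: int) -> tuple[float, float]:
    """Lower-left corner (lon, lat) of grid cell ``idx`` (row-major)."""
    row, col = divmod(idx, side)
    return float(col), float(row)


def _generate_geography(cfg: WorldConfig, rng, tweets: list[dict], z: np.ndarray
                        ) -> tuple[dict, WorldTruth]:
    n_areas = cfg.n_areas
    side = math.ceil(math.sqrt(n_areas))
    area_ids = [f"a{i:03d}" for i in range(n_areas)]

    base_pop = rng.lognormal(mean=math.log(10_000.0), sigma=0.5, size=n_areas)
    jitter = rng.uniform(0.95, 1.05, size=(n_areas, len(cfg.years)))
    pop_by_year = np.rint(base_pop[:, None] * jitter).astype(int)
    pop_by_year = np.maximum(pop_by_year, 1)
    mean_pop = pop_by_year.mean(axis=1)

    probs = base_pop / base_pop.sum()
    n = len(tweets)
    area_idx = rng.choice(n_areas, size=n, p=probs)
    geotagged = rng.random(n) < cfg.geotag_rate
    u = rng.random(n)
    v = rng.random(n)
    for i, tw in enumerate(tweets):
        if geotagged[i]:
            lon0, lat0 = _cell_bounds(int(area_idx[i]), side)
            tw["lon"] = float(lon0 + u[i])
            tw["lat"] = float(lat0 + v[i])

    total_counts = np.bincount(area_idx, minlength=n_areas)
    latent_counts = np.bincount(area_idx[z], minlength=n_areas)
    geo_counts = np.bincount(area_idx[geotagged], minlength=n_areas)
    geo_latent = np.bincount(area_idx[z & geotagged], minlength=n_areas)

    with np.errstate(invalid="ignore"):
        latent_rate = np.where(total_counts > 0, latent_counts / np.maximum(total_counts, 1), 0.0)
    latent_per10k = geo_latent / mean_pop * PREVALENCE_SCALE

    X = rng.standard_normal((n_areas, len(CONFOUNDER_FIELDS)))
    effects = np.asarray(cfg.confounder_effects, dtype=float)
    noise = rng.normal(0.0, cfg.noise_sd, n_areas)
    noise_ind = rng.normal(0.0, cfg.noise_sd, n_areas)
    y = cfg.intercept + cfg.true_beta * latent_per10k + X @ effects + noise
    y_ind = cfg.intercept + X @ effects + noise_ind  # no latent-activity term

    features = []
    for i, aid in enumerate(area_ids):
        lon0, lat0 = _cell_bounds(i, side)
        ring = [[lon0, lat0], [lon0 + 1.0, lat0], [lon0 + 1.0, lat0 + 1.0],
                [lon0, lat0 + 1.0], [lon0, lat0]]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "area_id": aid,
                "level": "county",
                "population": {str(yr): int(pop_by_year[i, j])
                               for j, yr in enumerate(cfg.years)},
                "confounders": {name: float(X[i, j])
                                for j, name in enumerate(CONFOUNDER_FIELDS)},
                "outcomes": {"alcohol_outcome": float(y[i]),
                             "independent_outcome": float(y_ind[i])},
            },
        })
    areas_geojson = {"type": "FeatureCollection", "features": features}

    truth = WorldTruth(
        planted_hashtags=list(cfg.planted_hashtags),
        true_beta=cfg.true_beta,
        area_latent_rate={aid: float(latent_rate[i]) for i, aid in enumerate(area_ids)},
        area_latent_per10k={aid: float(latent_per10k[i]) for i, aid in enumerate(area_ids)},
        area_geotagged_counts={aid: int(geo_counts[i]) for i, aid in enumerate(area_ids)},
        theme_communities=list(cfg.theme_communities),
        seed_community=cfg.seed_community,
    )
    return areas_geojson, truth


def generate_world(config: WorldConfig) -> World:
    """Generate posts, link graph, tweets, areas and truth from ``config``.

    Deterministic: the same config (including its seed) always produces the
    same world, independently of call order elsewhere in the process.
    """
    config.validate()
    posts, edges = _generate_posts(config, stream_rng(config.seed, "posts"))
    tweets, z = _generate_tweets(config, stream_rng(config.seed, "tweets"))
    areas, truth = _generate_geography(config, stream_rng(config.seed, "geography"),
                                       tweets, z)
    return World(config=config, posts=posts, graph_edges=edges, tweets=tweets,
                 areas_geojson=areas, truth=truth)


def write_world(world: World, directory) -> dict[str, Path]:
    """Write posts.jsonl, graph.tsv, tweets.jsonl, areas.geojson, truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "posts": directory / "posts.jsonl",
        "graph": directory / "graph.tsv",
        "tweets": directory / "tweets.jsonl",
        "areas": directory / "areas.geojson",
        "truth": directory / "truth.json",
    }
    io.write_jsonl(world.posts, paths["posts"])
    io.write_edge_list(world.graph_edges, paths["graph"])
    io.write_jsonl(world.tweets, paths["tweets"])
    io.write_json(world.areas_geojson, paths["areas"])
    io.write_json(world.truth.to_dict(), paths["truth"])
    return paths
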
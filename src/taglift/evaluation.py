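"""Replicated synthetic-world experiments quantifying pipeline operating
characteristics: planted-hashtag recovery, selection behavior under the
null, and adjusted-regression effect recovery.

Each experiment regenerates independent worlds from seeds derived off one
base seed, runs the relevant stages from scratch, and summarizes across
replicates. Problem sizes follow the default study conditions
(:class:`~taglift.synthetic_world.WorldConfig`); the effect-recovery
replicates shrink only the community-post count, which the estimator never
touches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .association import adjusted_regression
from .corpus_builder import (CommunityGraph, build_labeled_corpus,
                             expand_seed_communities, split_corpus)
from .geo_prevalence import load_areas
from .hashtag_discovery import discover
from .synthetic_world import World, WorldConfig, generate_world
from .text_classifier import train_classifier


def run_discovery_on_world(world: World, base_seed: int):
    """Corpus -> train -> discover on one world; returns the DiscoveryResult."""
    graph = CommunityGraph.from_posts(world.posts, world.graph_edges)
    positive = expand_seed_communities(graph, world.config.seed_community,
                                       min_posts=1000)
    corpus = build_labeled_corpus(world.posts, positive,
                                  seed=derive_seed(base_seed, "corpus"))
    split = split_corpus(corpus, seed=derive_seed(base_seed, "split"))
    model = train_classifier(split.train)
    return discover(world.tweets, model, q=0.05, min_count=5)


@dataclass
class RecoverySummary:
    mean_sensitivity: float
    mean_fdr: float
    per_seed_sensitivity: list[float]
    per_seed_fdr: list[float]


def planted_recovery_experiment(n_seeds: int = 20, base_seed: int = 0
                                ) -> RecoverySummary:
    """Sensitivity and empirical FDR of hashtag discovery on default worlds."""
    sens, fdrs = [], []
    for i in range(n_seeds):
        seed = derive_seed(base_seed, f"recovery:{i}")
        world = generate_world(WorldConfig(seed=seed))
        result = run_discovery_on_world(world, seed)
        planted = set(world.truth.planted_hashtags)
        selected = set(result.significant)
        sens.append(len(selected & planted) / len(planted))
        fdrs.append(len(selected - planted) / max(1, len(selected)))
    return RecoverySummary(float(np.mean(sens)), float(np.mean(fdrs)),
                           sens, fdrs)


@dataclass
class NullCalibrationSummary:
    mean_selected_fraction: float
    monte_carlo_se: float
    per_seed_fraction: list[float]


def null_calibration_experiment(n_seeds: int = 100, base_seed: int = 0,
                                shared_rate: float = 0.02
                                ) -> NullCalibrationSummary:
    """Selected fraction of tested hashtags when q1 == q0 (no signal)."""
    fractions = []
    for i in range(n_seeds):
        seed = derive_seed(base_seed, f"null:{i}")
        cfg = WorldConfig(planted_rate_pos=shared_rate,
                          planted_rate_neg=shared_rate, seed=seed)
        world = generate_world(cfg)
        result = run_discovery_on_world(world, seed)
        n_tested = len(result.results)
        fractions.append(len(result.significant) / n_tested if n_tested else 0.0)
    fractions = list(map(float, fractions))
    se = float(np.std(fractions, ddof=1) / np.sqrt(len(fractions)))
    return NullCalibrationSummary(float(np.mean(fractions)), se, fractions)


@dataclass
class EffectRecoverySummary:
    true_beta: float
    mean_beta: float
    monte_carlo_se: float
    ci_coverage: float
    per_rep_beta: list[float]


def effect_recovery_experiment(n_reps: int = 200, base_seed: int = 0
                               ) -> EffectRecoverySummary:
    """Adjusted OLS recovery of the generator's true_beta.

    Each replicate regresses the generated outcome on the true per-10k
    latent-tweet prevalence plus the seven confounders, recording the
    prevalence coefficient and whether its 95% CI covers true_beta.
    Community posts play no role here, so replicates carry a reduced
    posts_per_community.
    """
    betas, covered = [], []
    true_beta = WorldConfig().true_beta
    for i in range(n_reps):
        seed = derive_seed(base_seed, f"effect:{i}")
        cfg = WorldConfig(posts_per_community=50, seed=seed)
        world = generate_world(cfg)
        areas = load_areas(world.areas_geojson)
        prev = np.array([world.truth.area_latent_per10k[a.area_id]
                         for a in areas])
        y = np.array([a.outcomes["alcohol_outcome"] for a in areas])
        conf = pd.DataFrame([a.confounders for a in areas])
        beta, _, diag = adjusted_regression(prev, y, conf)
        betas.append(float(beta))
        lo, hi = diag.conf_int
        covered.append(lo <= cfg.true_beta <= hi)
    se = float(np.std(betas, ddof=1) / np.sqrt(len(betas)))
    return EffectRecoverySummary(true_beta, float(np.mean(betas)), se,
                                 float(np.mean(covered)), betas)
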
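#!/usr/bin/env python
"""Generate the default synthetic world and write its corpora to disk.

The world plants 15 enriched hashtags among 185 null ones, gives 18 of 40
communities an elevated theme-token rate, and ties each area's outcome to
its latent alcohol-tweet prevalence with coefficient true_beta = 2. All
later steps read the files written here.
"""

from pathlib import Path

from taglift.synthetic_world import WorldConfig, generate_world, write_world

# bulky regenerable corpora live under scratch/, never in results/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "world"
SEED = 20_130_601


def main() -> None:
    cfg = WorldConfig(seed=SEED)
    world = generate_world(cfg)
    paths = write_world(world, OUT)
    n_geo = sum(1 for t in world.tweets if "lat" in t)
    print(f"world written to {OUT}")
    print(f"  {len(world.posts)} posts across {cfg.n_communities} communities "
          f"({cfg.n_alcohol_communities} themed)")
    print(f"  {len(world.tweets)} tweets, {n_geo} geotagged, "
          f"{cfg.n_planted_hashtags} planted hashtags")
    print(f"  {cfg.n_areas} areas, true_beta={cfg.true_beta}")
    print("files:", ", ".join(p.name for p in paths.values()))


if __name__ == "__main__":
    main()
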
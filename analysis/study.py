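"""Shared study configuration for the analysis drivers.

One synthetic world stands in for the real study system: 60 species on a
60x60 pixel 2.5 arc-minute climate raster, with the generator's default
arboreal niche shift (warmer, lower-elevation, higher-PET optima for
arboreal species). All drivers derive their seeds from STUDY_SEED.
"""

from arborclim.pipeline import RunConfig
from arborclim.synthetic_world import WorldConfig

STUDY_SEED = 20260926

RESULTS = "results"


def study_world(seed: int = STUDY_SEED) -> WorldConfig:
    return WorldConfig(
        n_species=60,
        grid_rows=60,
        grid_cols=60,
        points_per_species=(20, 60),
        gain_rate=0.5,  # enough arboreal species for the pair analyses
        loss_rate=1.0,
        seed=seed,
    )


def study_run_config(seed: int = STUDY_SEED, **kw) -> RunConfig:
    kw.setdefault("n_perm", 999)
    return RunConfig(world=study_world(seed), seed=seed, **kw)
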
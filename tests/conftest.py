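import numpy as np
import pytest

from arborclim.raster import VARIABLE_CODES, ClimateRaster
from arborclim.synthetic_world import WorldConfig, generate_climate_raster


@pytest.fixture(scope="session")
def small_raster() -> ClimateRaster:
    """Deterministic 30x30 synthetic raster shared across tests."""
    cfg = WorldConfig(grid_rows=30, grid_cols=30, seed=7)
    return generate_climate_raster(cfg)


@pytest.fixture()
def flat_raster() -> ClimateRaster:
    """A tiny raster with hand-set values for exact-extraction tests."""
    rng = np.random.default_rng(0)
    values = rng.uniform(0, 100, size=(len(VARIABLE_CODES), 4, 5))
    values[VARIABLE_CODES.index("Elev")] = np.abs(
        values[VARIABLE_CODES.index("Elev")]
    )
    return ClimateRaster(
        values=values,
        lon_origin=-10.0,
        lat_origin=5.0,
        pixel_size=30.0,  # 0.5 degree pixels
    )
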
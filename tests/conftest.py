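import numpy as np
import pytest

from lerisk import LandCoverRaster, ScenarioConfig, build_grid, oasis_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced desert-oasis landscape (30 x 30 km at 250 m) for pipeline tests."""
    cfg = ScenarioConfig(
        shape=(120, 120),
        cell_size=250.0,
        origin=(0.0, 30_000.0),
        river_points_km=((0.0, 17.0), (8.0, 20.0), (16.0, 16.5), (22.0, 19.0)),
        lake_center_km=(25.0, 18.0),
        lake_radius_km=1.6,
        corridor_width_km=0.5,
        halo_width_km=1.5,
        cropland_sites_km=((6.0, 14.5, 1.2), (14.0, 13.5, 1.0)),
        town_sites_km=((6.6, 12.7, 0.45),),
        seed=7,
    )
    raster, truth = oasis_scenario(cfg)
    return cfg, raster, truth


@pytest.fixture()
def uniform_raster():
    """10 x 10 km single-class (wasteland) raster at 100 m pixels."""
    return LandCoverRaster(
        np.full((100, 100), 5, dtype=np.int32), 100.0, (0.0, 10_000.0)
    )


@pytest.fixture()
def uniform_grid(uniform_raster):
    return build_grid(uniform_raster, 2500.0)


def random_raster(shape=(20, 20), codes=(3, 5), seed=0, cell_size=500.0):
    rng = np.random.default_rng(seed)
    vals = rng.choice(codes, size=shape).astype(np.int32)
    return LandCoverRaster(vals, cell_size, (0.0, shape[0] * cell_size))
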
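import numpy as np
import pytest

from porecolony.geometry import PoreMask, discretize
from porecolony.synthetic import GeometryParams, generate_geometry


@pytest.fixture(scope="session")
def channel_mask():
    """Straight horizontal channel, width 24 px, between solid walls."""
    grid = np.zeros((40, 60), dtype=bool)
    grid[8:32, :] = True
    return PoreMask(grid=grid, pixel_size=1.0)


@pytest.fixture(scope="session")
def cavity_mask():
    """Horizontal channel with one deep side cavity carved into the lower grain.

    Channel rows 6..15 (width 10); cavity: 8 px wide, 30 px deep, opening
    upward into the channel at columns 26..33.
    """
    grid = np.zeros((60, 64), dtype=bool)
    grid[6:16, :] = True
    grid[16:46, 26:34] = True
    return PoreMask(grid=grid, pixel_size=1.0)


@pytest.fixture(scope="session")
def toy_params():
    """Scaled-down generator parameters used across closed-loop tests."""
    return dict(
        domain_size_px=(256, 320),
        pixel_size=4.0,
        target_porosity=0.35,
        target_dep_fraction=0.08,
        mean_pore_size=0.04,
        mean_dep_depth=0.1,
        cavity_aspect=3.0,
    )


@pytest.fixture(scope="session")
def toy_scene(toy_params):
    params = GeometryParams(seed=1, **toy_params)
    mask, truth = generate_geometry(params)
    return mask, truth


@pytest.fixture(scope="session")
def toy_discretized(toy_scene):
    mask, truth = toy_scene
    lmap, skel, disks, grains = discretize(mask)
    return mask, truth, lmap, skel, disks, grains
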
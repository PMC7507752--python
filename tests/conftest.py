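import logging

import numpy as np
import pandas as pd
import pytest

from canopy2cohorts import synthetic
from canopy2cohorts.allometry import default_allometry
from canopy2cohorts.profiles import CanopyProfile, PointCloudColumn

logging.getLogger("canopy2cohorts").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def allom():
    return default_allometry()


@pytest.fixture(scope="session")
def small_scene():
    """One seeded 0.25-ha synthetic stand with its point cloud."""
    cfg = synthetic.SyntheticStandConfig(stem_density=480.0, rng_seed=7)
    return synthetic.generate_scene(cfg, pulse_density=4.0)


@pytest.fixture(scope="session")
def scene_column(small_scene):
    side = float(np.sqrt(small_scene.config.plot_area))
    return PointCloudColumn(
        column_id="c0_0", x_range=(0.0, side), y_range=(0.0, side),
        points=small_scene.point_cloud,
    )


def make_profile(lad, dz=1.0, column_id=""):
    lad = np.asarray(lad, dtype=float)
    edges = np.arange(0.0, (len(lad) + 0.5) * dz, dz)[:len(lad) + 1]
    return CanopyProfile(edges=edges, lad=lad, column_id=column_id)


@pytest.fixture
def profile_factory():
    return make_profile


def make_column(xyz, column_id="c", is_ground=None):
    xyz = np.asarray(xyz, dtype=float)
    df = pd.DataFrame(xyz, columns=["x", "y", "z"])
    df["return_number"] = 1
    if is_ground is not None:
        df["is_ground"] = is_ground
    x0, x1 = df["x"].min(), df["x"].max() + 1.0
    y0, y1 = df["y"].min(), df["y"].max() + 1.0
    return PointCloudColumn(column_id=column_id, x_range=(x0, x1),
                            y_range=(y0, y1), points=df)


@pytest.fixture
def column_factory():
    return make_column
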
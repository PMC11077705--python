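import numpy as np
import pytest

from orchard_qsm.pointcloud_io import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid_cloud():
    """5x5x4 = 100 points on a regular grid with spacing 0.1 m."""
    g = np.stack(np.meshgrid(np.arange(5), np.arange(5), np.arange(4),
                             indexing="ij"), axis=-1).reshape(-1, 3) * 0.1
    return PointCloud(g)


def cylinder_cloud(radius=0.025, height=1.0, n=3000, sigma=0.0, seed=0,
                   center=(0.0, 0.0, 0.0), axis_z=True):
    """Points on a cylinder surface, optionally noisy."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, height, n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    if sigma > 0:
        pts = pts + rng.normal(0, sigma, pts.shape)
    return PointCloud(pts + np.asarray(center))
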
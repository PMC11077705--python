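"""Structure-aware downsampling along a 3D Hilbert space-filling curve.

A tree cloud normalized to the unit cube is rasterized onto the 2^k x 2^k x 2^k
grid of the order-k Hilbert curve H_k.  Each occupied grid cell becomes one
histogram bin on the 1D curve and contributes an (almost) equal quota of points
to the downsampled cloud, so sparse structures — thin branches, occluded
junction shoulders — keep representation that plain random sampling would wash
out, while the over-sampled trunk sheds points.

The cell <-> curve-index bijection uses the bit-transpose formulation of the
Hilbert encoding (Gray-code based), vectorized over all points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .pointcloud_io import PointCloud

__all__ = [
    "HilbertConfig",
    "CurveHistogram",
    "hilbert_index",
    "hilbert_inverse",
    "map_points_to_curve",
    "per_bin_quota",
    "downsample",
]


@dataclass
class HilbertConfig:
    order: int = 7          # k of H_k: grid is (2^k)^3 cells
    target_points: int = 50_000  # N_S, the post-downsampling budget
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.order <= 10:
            raise ValueError("order must lie in [1, 10]")
        if self.target_points < 1:
            raise ValueError("target_points must be >= 1")


@dataclass
class CurveHistogram:
    bin_ids: np.ndarray                      # per-point 1D Hilbert block index
    bin_members: Dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def nonempty_bins(self) -> int:
        return len(self.bin_members)


# ---------------------------------------------------------------------------
# encode / decode (transpose form, 3D)
# ---------------------------------------------------------------------------

def _axes_to_transpose(x: np.ndarray, order: int) -> np.ndarray:
    """Map grid cells (m, 3) to the transposed Hilbert form, in place-free style."""
    x = x.astype(np.int64).copy()
    m = 1 << (order - 1)
    # inverse undo excess work
    q = m
    while q > 1:
        p = q - 1
        for i in range(3):
            hit = (x[:, i] & q) != 0
            x[hit, 0] ^= p
            t = (x[~hit, 0] ^ x[~hit, i]) & p
            x[~hit, 0] ^= t
            x[~hit, i] ^= t
        q >>= 1
    # Gray encode
    for i in range(1, 3):
        x[:, i] ^= x[:, i - 1]
    t = np.zeros(len(x), dtype=np.int64)
    q = m
    while q > 1:
        hit = (x[:, 2] & q) != 0
        t[hit] ^= q - 1
        q >>= 1
    x ^= t[:, None]
    return x


def _transpose_to_axes(x: np.ndarray, order: int) -> np.ndarray:
    x = x.astype(np.int64).copy()
    n_cells = 2 << (order - 1)
    # Gray decode
    t = x[:, 2] >> 1
    for i in range(2, 0, -1):
        x[:, i] ^= x[:, i - 1]
    x[:, 0] ^= t
    # undo excess work
    q = 2
    while q != n_cells:
        p = q - 1
        for i in range(2, -1, -1):
            hit = (x[:, i] & q) != 0
            x[hit, 0] ^= p
            t = (x[~hit, 0] ^ x[~hit, i]) & p
            x[~hit, 0] ^= t
            x[~hit, i] ^= t
        q <<= 1
    return x


def hilbert_index(cell, order: int) -> np.ndarray | int:
    """1D Hilbert index of 3D grid cell(s) at the given curve order.

    ``cell`` is an integer 3-vector or (m, 3) array with coordinates in
    [0, 2^order - 1]; returns indices in [0, 8^order - 1].
    """
    arr = np.atleast_2d(np.asarray(cell, dtype=np.int64))
    if arr.shape[1] != 3:
        raise ValueError("cells must be 3D")
    if np.any(arr < 0) or np.any(arr >= (1 << order)):
        raise ValueError(f"cell coordinates out of [0, {(1 << order) - 1}]")
    tr = _axes_to_transpose(arr, order)
    # interleave bits: for bit position b (msb first), axes x,y,z in order
    out = np.zeros(len(arr), dtype=np.int64)
    for b in range(order - 1, -1, -1):
        for i in range(3):
            out = (out << 1) | ((tr[:, i] >> b) & 1)
    return out if np.asarray(cell).ndim == 2 else int(out[0])

def hilbert_inverse(index, order: int) -> np.ndarray:
    """Grid cell(s) of 1D Hilbert index/indices; inverse of :func:`hilbert_index`."""
    idx = np.atleast_1d(np.asarray(index, dtype=np.int64))
    if np.any(idx < 0) or np.any(idx >= (1 << (3 * order))):
        raise ValueError("index out of range")
    tr = np.zeros((len(idx), 3), dtype=np.int64)
    for b in range(order):
        for i in range(3):
            shift = 3 * (order - 1 - b) + (2 - i)
            tr[:, i] |= ((idx >> shift) & 1) << (order - 1 - b)
    axes = _transpose_to_axes(tr, order)
    return axes if np.asarray(index).ndim >= 1 else axes[0]


# ---------------------------------------------------------------------------
# histogram + quota selection
# ---------------------------------------------------------------------------

def map_points_to_curve(cloud: PointCloud, config: HilbertConfig) -> CurveHistogram:
    """Assign each point of a [0,1]^3-normalized cloud to its Hilbert bin."""
    coords = cloud.coords
    if coords.size and (coords.min() < -1e-12 or coords.max() > 1 + 1e-12):
        raise ValueError("map_points_to_curve expects coordinates in [0, 1]^3")
    side = 1 << config.order
    cells = np.clip((coords * side).astype(np.int64), 0, side - 1)
    ids = np.asarray(hilbert_index(cells, config.order))
    members: Dict[int, np.ndarray] = {}
    order_ix = np.argsort(ids, kind="stable")
    sorted_ids = ids[order_ix]
    bounds = np.flatnonzero(np.diff(sorted_ids)) + 1
    for chunk in np.split(order_ix, bounds):
        if len(chunk):
            members[int(ids[chunk[0]])] = chunk
    return CurveHistogram(bin_ids=ids, bin_members=members)


def per_bin_quota(target_points: int, nonempty_bins: int) -> int:
    """N_h = floor(N_S / #Bins), clamped to at least one point per bin."""
    if target_points < 1 or nonempty_bins < 1:
        raise ValueError("both arguments must be >= 1")
    return max(1, target_points // nonempty_bins)


def downsample(cloud: PointCloud, config: HilbertConfig) -> PointCloud:
    """Hilbert-histogram downsampling to roughly ``target_points`` points.

    Each nonempty bin contributes min(N_h, bin size) points drawn uniformly
    without replacement (seeded); leftover budget is redistributed one point at
    a time to the largest bins (ties: smaller bin id).  Clouds already within
    budget pass through unchanged.  Output order follows the original cloud.
    """
    if cloud.n <= config.target_points:
        return cloud
    hist = map_points_to_curve(cloud, config)
    n_h = per_bin_quota(config.target_points, hist.nonempty_bins)
    take = {b: min(n_h, len(m)) for b, m in hist.bin_members.items()}
    leftover = config.target_points - sum(take.values())
    if leftover > 0:
        by_size = sorted(hist.bin_members, key=lambda b: (-len(hist.bin_members[b]), b))
        while leftover > 0:
            progress = False
            for b in by_size:
                if take[b] < len(hist.bin_members[b]):
                    take[b] += 1
                    leftover -= 1
                    progress = True
                    if leftover == 0:
                        break
            if not progress:
                break
    rng = np.random.default_rng(config.seed)
    chosen = []
    for b in sorted(hist.bin_members):
        members = hist.bin_members[b]
        k = take[b]
        if k >= len(members):
            chosen.append(members)
        else:
            chosen.append(rng.choice(members, size=k, replace=False))
    index = np.sort(np.concatenate(chosen))
    return cloud.select(index)
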
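"""Laplacian contraction skeletonization with FPS thinning.

The downsampled cloud is contracted toward its medial structure by repeatedly
solving the stacked linear system

    [ W_L . L ]        [   0    ]
    [ W_H . I ] X'  =  [ W_H X ]

where L is the (row-normalized) combinatorial Laplacian of the k-NN graph of
the current positions, W_L is a global contraction weight that grows every
iteration and W_H is a per-point attraction weight that grows as a point's
neighborhood shrinks, anchoring already-contracted regions.  The contracted
cloud is thinned with farthest point sampling at a resolution epsilon chosen
from the bounding-box diagonal, connectivity is inherited from the k-NN
structure of the supports, and edges are collapsed until the graph is
triangle-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .pointcloud_io import PointCloud

__all__ = [
    "ContractionParams",
    "SkeletonGraph",
    "contract",
    "adaptive_fps_resolution",
    "fps_thinning",
    "build_connectivity",
    "collapse_edges",
]


@dataclass
class ContractionParams:
    neighborhood_k: int = 8
    initial_contraction_weight: float = 1.0
    initial_attraction_weight: float = 1.0
    weight_growth_factor: float = 2.0
    max_iterations: int = 10
    convergence_ratio: float = 0.01

    def __post_init__(self) -> None:
        if self.weight_growth_factor <= 1:
            raise ValueError("weight_growth_factor must be > 1")
        if not 0 < self.convergence_ratio < 1:
            raise ValueError("convergence_ratio must lie in (0, 1)")


@dataclass
class SkeletonGraph:
    """Thinned skeleton: vertices, undirected edges and per-vertex support.

    ``support[v]`` lists the indices of the contracted/original points the
    vertex represents; supports partition the input cloud.
    """

    vertices: np.ndarray
    edges: List[tuple] = field(default_factory=list)
    support: List[np.ndarray] = field(default_factory=list)
    fps_resolution: float = 0.0

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "SkeletonGraph":
        return SkeletonGraph(self.vertices.copy(), list(self.edges),
                             [s.copy() for s in self.support], self.fps_resolution)


# ---------------------------------------------------------------------------
# contraction
# ---------------------------------------------------------------------------

def _knn_laplacian(coords: np.ndarray, k: int) -> sparse.csr_matrix:
    """Row-normalized Laplacian of the symmetrized k-NN graph: (L X)_i = mean(nbrs) - x_i."""
    n = len(coords)
    tree = cKDTree(coords)
    _, nbrs = tree.query(coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = nbrs[:, 1:].ravel()
    adj = sparse.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    adj = ((adj + adj.T) > 0).astype(np.float64)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    inv_deg = sparse.diags(1.0 / deg)
    return (inv_deg @ adj - sparse.eye(n)).tocsr()


def _local_extent(coords: np.ndarray, k: int) -> np.ndarray:
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=k + 1)
    return d[:, 1:].mean(axis=1)


def contract(cloud: PointCloud, params: ContractionParams = ContractionParams(),
             return_history: bool = False):
    """Contract a cloud toward its medial structure; same n, moved positions."""
    n = cloud.n
    k = params.neighborhood_k
    if n < k + 1:
        raise ValueError(f"contract needs n >= neighborhood_k + 1 ({n} < {k + 1})")
    x = cloud.coords.copy()
    extent0 = _local_extent(x, k)
    # neighborhood topology is fixed from the input cloud: rebuilding it from
    # contracted positions freezes the flow once points clump along filaments
    lap = _knn_laplacian(x, k)
    w_l = params.initial_contraction_weight
    w_h = np.full(n, params.initial_attraction_weight)
    history = [x.copy()]
    for iteration in range(params.max_iterations):
        a_top = lap.multiply(w_l)
        a_bot = sparse.diags(w_h)
        normal = (a_top.T @ a_top + a_bot.power(2)).tocsc()
        rhs = a_bot.power(2) @ x
        try:
            solver = splu(normal)
        except RuntimeError as exc:  # pragma: no cover - singular systems are rare
            raise RuntimeError(f"contraction system singular at iteration {iteration}") from exc
        x_new = np.column_stack([solver.solve(rhs[:, d]) for d in range(3)])
        if not np.all(np.isfinite(x_new)):
            raise RuntimeError(f"contraction diverged at iteration {iteration}")
        x = x_new
        history.append(x.copy())
        extent = _local_extent(x, k)
        shrink = extent / np.maximum(extent0, 1e-300)
        if shrink.mean() < params.convergence_ratio:
            break
        w_l *= params.weight_growth_factor
        # attraction grows as the reciprocal of the achieved local shrink ratio
        w_h = params.initial_attraction_weight / np.clip(shrink, 1e-1, None)
    out = PointCloud(x, cloud.color)
    return (out, history) if return_history else out


# ---------------------------------------------------------------------------
# thinning + connectivity
# ---------------------------------------------------------------------------

def adaptive_fps_resolution(cloud: PointCloud, c_fps: float = 0.015) -> float:
    """Sampling resolution epsilon = c_fps * bounding-box diagonal (meters)."""
    if cloud.n == 0:
        raise ValueError("empty cloud")
    extent = cloud.coords.max(axis=0) - cloud.coords.min(axis=0)
    diag = float(np.linalg.norm(extent))
    if diag <= 0:
        raise ValueError("degenerate input: zero extent")
    return c_fps * diag


def fps_thinning(contracted: PointCloud, epsilon: float,
                 start: Optional[int] = None) -> SkeletonGraph:
    """Farthest point sampling until every point lies within epsilon of a sample.

    The start sample is the point nearest the lowest-z point of the cloud
    (ties: smallest index), anchoring the skeleton at the tree root and making
    the greedy sweep deterministic.  Each point's support assignment is its
    nearest sample.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    coords = contracted.coords
    n = len(coords)
    if start is None:
        start = int(np.argmin(coords[:, 2]))
    samples = [start]
    min_d = np.linalg.norm(coords - coords[start], axis=1)
    assign = np.zeros(n, dtype=np.int64)
    while True:
        far = int(np.argmax(min_d))
        if min_d[far] <= epsilon:
            break
        samples.append(far)
        d_new = np.linalg.norm(coords - coords[far], axis=1)
        closer = d_new < min_d
        min_d[closer] = d_new[closer]
        assign[closer] = len(samples) - 1
    support = [np.flatnonzero(assign == s) for s in range(len(samples))]
    return SkeletonGraph(vertices=coords[samples], support=support,
                         fps_resolution=float(epsilon))


def build_connectivity(skeleton: SkeletonGraph, contracted: PointCloud,
                       neighborhood_k: int = 8) -> SkeletonGraph:
    """Inherit edges from the k-NN structure of the contracted points.

    An edge (u, v) exists iff some point in u's support is a k-NN neighbor of
    some point in v's support.
    """
    n = contracted.n
    owner = np.empty(n, dtype=np.int64)
    for v, sup in enumerate(skeleton.support):
        owner[sup] = v
    tree = cKDTree(contracted.coords)
    _, nbrs = tree.query(contracted.coords, k=min(neighborhood_k + 1, n))
    edges = set()
    for i in range(n):
        u = owner[i]
        for j in nbrs[i, 1:]:
            v = owner[j]
            if u != v:
                edges.add((min(u, v), max(u, v)))
    out = skeleton.copy()
    out.edges = sorted(edges)
    return out


def collapse_edges(skeleton: SkeletonGraph) -> SkeletonGraph:
    """Remove the longest edge of each 3-cycle until the graph is triangle-free.

    Ties in length are broken by removing the lexicographically larger vertex
    pair.  Removal is restricted to cycle edges, so connected components are
    preserved.
    """
    verts = skeleton.vertices
    edges = set(skeleton.edges)
    adjacency: dict[int, set] = {}
    for u, v in edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)

    def edge_len(e):
        return float(np.linalg.norm(verts[e[0]] - verts[e[1]]))

    changed = True
    while changed:
        changed = False
        for u, v in sorted(edges):
            if (u, v) not in edges:
                continue
            common = adjacency.get(u, set()) & adjacency.get(v, set())
            for w in sorted(common):
                tri = [(u, v), (min(u, w), max(u, w)), (min(v, w), max(v, w))]
                worst = max(tri, key=lambda e: (edge_len(e), e))
                edges.discard(worst)
                adjacency[worst[0]].discard(worst[1])
                adjacency[worst[1]].discard(worst[0])
                changed = True
                if worst == (u, v):
                    break
    out = skeleton.copy()
    out.edges = sorted(edges)
    return out
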
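"""Biology-aware weighted skeleton graph and optimal MST.

Edge weights combine local thickness — approximated by point density against
the original cloud, m_i = 1 / mean distance to the K nearest original points —
with Euclidean edge length:

    e_ij = alpha * (1/m_i + 1/m_j)/T + (1 - alpha) * d_ij / D

with T, D the maxima of the raw thickness and length terms over the candidate
edges, so both terms lie in (0, 1].  Edges are gated by a distance threshold
d_th: missing links between proximate vertices are created and spurious links
between distant vertices removed.  The minimum spanning tree of the largest
connected component ("optimal MST") is the coarse tree skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud_io import PointCloud
from .skeletonize import SkeletonGraph

__all__ = [
    "BAGraphParams",
    "WeightedSkeletonGraph",
    "point_density",
    "ba_edge_weight",
    "build_ba_graph",
    "optimal_mst",
]

DENSITY_CAP = 1e6  # m^-1, density assigned when all K neighbors coincide


@dataclass
class BAGraphParams:
    alpha: float = 0.5
    distance_threshold: Optional[float] = None  # d_th (m); None -> 3x median NN spacing
    density_neighbors: int = 150                # K of the thickness proxy; the
    # probe must reach beyond one structure radius or it measures 1/radius

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class WeightedSkeletonGraph:
    vertices: np.ndarray
    density: np.ndarray
    edges: Dict[Tuple[int, int], float] = field(default_factory=dict)
    params: BAGraphParams = field(default_factory=BAGraphParams)
    support: List[np.ndarray] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def neighbor_map(self) -> Dict[int, list]:
        adj: Dict[int, list] = {i: [] for i in range(self.n_vertices)}
        for (u, v), w in self.edges.items():
            adj[u].append((v, w))
            adj[v].append((u, w))
        return adj


def point_density(original: PointCloud, query, K: int = 5) -> float | np.ndarray:
    """Density proxy for thickness: reciprocal of the mean K-NN distance in P."""
    if original.n < K:
        raise ValueError(f"point_density needs >= K points ({original.n} < {K})")
    q = np.atleast_2d(np.asarray(query, dtype=np.float64))
    tree = cKDTree(original.coords)
    d, _ = tree.query(q, k=K)
    d = d.reshape(len(q), K)
    mean_d = d.mean(axis=1)
    out = np.where(mean_d > 0, 1.0 / np.maximum(mean_d, 1e-300), DENSITY_CAP)
    return out if np.asarray(query).ndim == 2 else float(out[0])


def ba_edge_weight(m_i: float, m_j: float, d_ij: float, alpha: float,
                   norm_thickness: float, norm_length: float) -> float:
    """Edge weight from reciprocal-density thickness and length terms."""
    thickness = (1.0 / m_i + 1.0 / m_j) / norm_thickness
    return alpha * thickness + (1.0 - alpha) * d_ij / norm_length


def _candidate_edges(vertices: np.ndarray, inherited, d_th: float):
    tree = cKDTree(vertices)
    pairs = {(min(u, v), max(u, v)) for u, v in tree.query_pairs(d_th)}
    for u, v in inherited:
        key = (min(u, v), max(u, v))
        if np.linalg.norm(vertices[u] - vertices[v]) < d_th:
            pairs.add(key)
    return sorted(pairs)


def default_distance_threshold(vertices: np.ndarray) -> float:
    """3x the median nearest-neighbor spacing of the skeleton vertices."""
    if len(vertices) < 2:
        return 1.0
    tree = cKDTree(vertices)
    d, _ = tree.query(vertices, k=2)
    return 3.0 * float(np.median(d[:, 1]))


def build_ba_graph(skeleton: SkeletonGraph, original: PointCloud,
                   params: BAGraphParams | None = None) -> WeightedSkeletonGraph:
    """Weight the skeleton with the biology-aware edge rule under the d_th gate."""
    params = params or BAGraphParams()
    if skeleton.n_vertices == 0:
        raise ValueError("empty skeleton")
    verts = skeleton.vertices
    d_th = params.distance_threshold or default_distance_threshold(verts)
    dens = np.asarray(point_density(original, verts, params.density_neighbors))
    pairs = _candidate_edges(verts, skeleton.edges, d_th)
    if pairs:
        arr = np.asarray(pairs)
        lengths = np.linalg.norm(verts[arr[:, 0]] - verts[arr[:, 1]], axis=1)
        thickness_raw = 1.0 / dens[arr[:, 0]] + 1.0 / dens[arr[:, 1]]
        norm_t = float(thickness_raw.max()) or 1.0
        norm_l = float(lengths.max()) or 1.0
        weights = params.alpha * thickness_raw / norm_t + (1 - params.alpha) * lengths / norm_l
        edges = {tuple(p): float(w) for p, w in zip(pairs, weights)}
    else:
        edges = {}
    return WeightedSkeletonGraph(vertices=verts, density=dens, edges=edges,
                                 params=params, support=list(skeleton.support))


# ---------------------------------------------------------------------------
# optimal MST
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_edges(n_vertices: int, edges: Dict[Tuple[int, int], float]):
    """Kruskal MST forest; ties broken by lexicographic vertex pair for determinism."""
    uf = _UnionFind(n_vertices)
    chosen = {}
    for (u, v), w in sorted(edges.items(), key=lambda item: (item[1], item[0])):
        if uf.union(u, v):
            chosen[(u, v)] = w
    return chosen, uf


def optimal_mst(graph: WeightedSkeletonGraph) -> WeightedSkeletonGraph:
    """MST of the connected component with the most vertices.

    Ties between equally large components go to the smaller total MST weight,
    then to the component whose root (lowest-z vertex) has smaller z.  Vertex
    indexing is preserved; vertices outside the winning component keep no
    edges and are excluded from downstream traversal via the component mask.
    """
    n = graph.n_vertices
    if n == 0:
        raise ValueError("empty graph")
    forest, uf = minimum_spanning_edges(n, graph.edges)
    comps: Dict[int, list] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)

    def comp_key(root):
        members = comps[root]
        weight = sum(w for (u, v), w in forest.items()
                     if uf.find(u) == root)
        zmin = min(graph.vertices[m][2] for m in members)
        return (-len(members), weight, zmin)

    best = min(comps, key=comp_key)
    members = set(comps[best])
    edges = {e: w for e, w in forest.items() if e[0] in members}
    out = WeightedSkeletonGraph(vertices=graph.vertices, density=graph.density,
                                edges=edges, params=graph.params,
                                support=list(graph.support))
    out.component = sorted(members)  # type: ignore[attr-defined]
    return out
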
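"""Trunk and primary-branch segmentation on the biology-aware skeleton tree.

The trunk is the maximal-weight root path under a reweighting that rewards
dense (thick) vertices; a tube of radius R around the trunk polyline isolates
branch origin vertices, which DBSCAN groups into origin clusters.  Clusters
are validated by extending a fitted 3D line toward the trunk (gap <= d_ext),
each valid cluster grows an entire branch as the optimal MST over the
unassigned skeleton, the primary branch is the maximal-weight path inside it,
and skeleton vertices claimed by several branches are arbitrated by maximum
direction matching (MDM): spectral clusters of conflicted vertices go to the
branch whose growth direction turns least.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import DBSCAN, SpectralClustering

from .ba_graph import WeightedSkeletonGraph, minimum_spanning_edges
from .pointcloud_io import PointCloud

__all__ = [
    "SegmentationParams",
    "TrunkWeights",
    "BranchOriginCluster",
    "BranchSegment",
    "TreeTopology",
    "reweight_for_trunk",
    "path_weights_from_root",
    "identify_trunk",
    "tube_prune",
    "cluster_branch_origins",
    "validate_origin_cluster",
    "grow_entire_branch",
    "extract_primary_branch",
    "mdm_resolve",
    "segment_tree",
]


@dataclass
class SegmentationParams:
    """Tube / clustering / validation parameters.

    ``None`` values are resolved per tree from the skeleton's FPS resolution
    epsilon: the skeleton vertex spacing sets the natural scale for how many
    vertices a branch leaves inside the trunk tube, so fixed metric values
    would silently under- or over-cluster at other resolutions.
    """

    tube_radius: Optional[float] = None        # R (m); default 4.5 * epsilon
    extension_threshold: Optional[float] = None  # d_ext (m); default 3.5 * epsilon
    dbscan_eps: Optional[float] = None         # default 2.0 * epsilon
    dbscan_min_pts: int = 1
    alpha: float = 0.5
    seed: int = 0
    epsilon: float = 0.0

    def resolved(self, epsilon: float) -> "SegmentationParams":
        # junction neighborhoods contract onto the trunk filament, so branch
        # filaments surface one to three vertex spacings away from the trunk;
        # the tube must reach past that shadow zone
        return SegmentationParams(
            tube_radius=self.tube_radius or max(0.10, 4.5 * epsilon),
            extension_threshold=self.extension_threshold or max(0.08, 3.5 * epsilon),
            dbscan_eps=self.dbscan_eps or max(0.04, 2.0 * epsilon),
            dbscan_min_pts=self.dbscan_min_pts,
            alpha=self.alpha,
            seed=self.seed,
            epsilon=epsilon,
        )


@dataclass
class TrunkWeights:
    reweighted_edges: Dict[Tuple[int, int], float]
    root_index: int
    path_weight: Dict[int, float] = field(default_factory=dict)
    path_predecessor: Dict[int, int] = field(default_factory=dict)


@dataclass
class BranchOriginCluster:
    member_indices: np.ndarray            # skeleton vertex indices, trunk -> outward order
    fitted_point: Optional[np.ndarray] = None
    fitted_direction: Optional[np.ndarray] = None
    extension_length: float = np.inf
    origin_estimate: Optional[np.ndarray] = None   # trunk closest-approach point
    valid: bool = False
    reason: str = ""


@dataclass
class BranchSegment:
    origin_cluster: BranchOriginCluster
    entire_branch: Dict[Tuple[int, int], float]   # tree subgraph edges
    vertices: List[int] = field(default_factory=list)
    primary_path: List[int] = field(default_factory=list)


@dataclass
class TreeTopology:
    trunk_path: List[int]
    branches: List[BranchSegment]
    skeleton: WeightedSkeletonGraph

    @property
    def branch_count(self) -> int:
        return len(self.branches)


# ---------------------------------------------------------------------------
# trunk identification
# ---------------------------------------------------------------------------

def reweight_for_trunk(tree: WeightedSkeletonGraph, alpha: float = 0.5,
                       edges: Optional[Dict[Tuple[int, int], float]] = None,
                       ) -> TrunkWeights:
    """e'_ij = alpha*(m_i+m_j)/T + (1-alpha)*d_ij/D over the tree edges.

    Unlike the MST stage, thickness enters directly (not reciprocally): the
    trunk is found as the *maximal*-weight root path, so dense vertices now
    attract the path.
    """
    pairs = sorted(edges if edges is not None else tree.edges)
    verts, dens = tree.vertices, tree.density
    if pairs:
        arr = np.asarray(pairs)
        lengths = np.linalg.norm(verts[arr[:, 0]] - verts[arr[:, 1]], axis=1)
        thick = dens[arr[:, 0]] + dens[arr[:, 1]]
        norm_t = float(thick.max()) or 1.0
        norm_l = float(lengths.max()) or 1.0
        vals = alpha * thick / norm_t + (1 - alpha) * lengths / norm_l
        rew = {tuple(p): float(v) for p, v in zip(pairs, vals)}
        members = sorted({v for e in pairs for v in e})
    else:
        rew, members = {}, list(range(tree.n_vertices))
    root = min(members, key=lambda i: (verts[i][2], i)) if members else 0
    return TrunkWeights(reweighted_edges=rew, root_index=root)


def path_weights_from_root(tree: WeightedSkeletonGraph, weights: TrunkWeights,
                           ) -> TrunkWeights:
    """Accumulate e' along the unique tree path from every vertex to the root."""
    adj: Dict[int, list] = {}
    for (u, v), w in weights.reweighted_edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    root = weights.root_index
    weights.path_weight = {root: 0.0}
    weights.path_predecessor = {root: root}
    stack = [root]
    while stack:
        u = stack.pop()
        for v, w in sorted(adj.get(u, [])):
            if v not in weights.path_weight:
                weights.path_weight[v] = weights.path_weight[u] + w
                weights.path_predecessor[v] = u
                stack.append(v)
    return weights


def identify_trunk(tree: WeightedSkeletonGraph, weights: TrunkWeights) -> List[int]:
    """Trunk = predecessor chain of the maximal-weight vertex, root -> top.

    Ties in path weight go to the vertex with higher z, then smaller index.
    """
    if not weights.path_weight:
        return []
    tip = min(weights.path_weight,
              key=lambda k: (-weights.path_weight[k], -tree.vertices[k][2], k))
    path = [tip]
    while path[-1] != weights.root_index:
        path.append(weights.path_predecessor[path[-1]])
    return path[::-1]


# ---------------------------------------------------------------------------
# tube pruning + origin clustering
# ---------------------------------------------------------------------------

def _point_to_polyline_distance(points: np.ndarray, polyline: np.ndarray,
                                return_points: bool = False):
    """Min distance from each point to a polyline (vectorized over segments)."""
    points = np.atleast_2d(points)
    if len(polyline) == 1:
        d = np.linalg.norm(points - polyline[0], axis=1)
        if return_points:
            return d, np.broadcast_to(polyline[0], points.shape).copy()
        return d
    a = polyline[:-1]                      # (s, 3)
    ab = polyline[1:] - a                  # (s, 3)
    denom = np.maximum((ab * ab).sum(axis=1), 1e-300)
    ap = points[:, None, :] - a[None, :, :]          # (m, s, 3)
    t = np.clip((ap * ab[None]).sum(axis=2) / denom, 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    if return_points:
        j = np.argmin(d, axis=1)
        rows = np.arange(len(points))
        return d[rows, j], closest[rows, j]
    return d.min(axis=1)


def tube_prune(tree: WeightedSkeletonGraph, trunk_path: Sequence[int],
               R: float, component: Optional[Sequence[int]] = None) -> List[int]:
    """Non-trunk vertices within distance R of the trunk polyline."""
    if not trunk_path:
        raise ValueError("empty trunk path")
    trunk_set = set(trunk_path)
    candidates = [i for i in (component if component is not None
                              else range(tree.n_vertices)) if i not in trunk_set]
    if not candidates:
        return []
    d = _point_to_polyline_distance(tree.vertices[candidates],
                                    tree.vertices[list(trunk_path)])
    return [c for c, di in zip(candidates, d) if di < R]


def cluster_branch_origins(tree: WeightedSkeletonGraph, near_vertices: Sequence[int],
                           eps: float, min_pts: int = 1) -> List[BranchOriginCluster]:
    """DBSCAN the tube vertices into branch origin groups, ordered by centroid z."""
    if not near_vertices:
        return []
    ids = np.asarray(sorted(near_vertices))
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(tree.vertices[ids])
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        members = ids[labels == lab]
        clusters.append(BranchOriginCluster(member_indices=members))
    clusters.sort(key=lambda c: tree.vertices[c.member_indices][:, 2].mean())
    return clusters


def _fit_line(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares 3D line: centroid + principal direction (unit)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    return centroid, direction / np.linalg.norm(direction)


def validate_origin_cluster(cluster: BranchOriginCluster,
                            tree: WeightedSkeletonGraph,
                            trunk_path: Sequence[int],
                            d_ext: float) -> BranchOriginCluster:
    """Extend the cluster's fitted line toward the trunk; keep if the gap is small.

    The extension length is the distance from the cluster's trunk-nearest
    member to the point where the fitted line comes closest to the trunk
    polyline, plus the residual line-to-trunk gap at that point, so clusters
    whose line never approaches the trunk (e.g. parallel offshoots of other
    branches) are rejected.
    """
    pts = tree.vertices[cluster.member_indices]
    if len(pts) < 2:
        cluster.valid = False
        cluster.reason = "fewer than 2 members"
        return cluster
    trunk = tree.vertices[list(trunk_path)]
    centroid, direction = _fit_line(pts)
    # order members from trunk outward along the line, keep fitted geometry
    d_trunk = _point_to_polyline_distance(pts, trunk)
    t_members = (pts - centroid) @ direction
    # orient the line so t grows away from the trunk (covariance sign test)
    if np.sum((t_members - t_members.mean()) * (d_trunk - d_trunk.mean())) < 0:
        direction = -direction
        t_members = -t_members
    order = np.argsort(t_members, kind="stable")
    cluster.member_indices = cluster.member_indices[order]
    cluster.fitted_point = centroid
    cluster.fitted_direction = direction
    # closest approach of the infinite line to the trunk polyline
    reach = 5 * d_ext if np.isfinite(d_ext) else 1.0
    ts = np.linspace(t_members.min() - reach, t_members.max(), 200)
    line_pts = centroid + ts[:, None] * direction
    gaps, closest = _point_to_polyline_distance(line_pts, trunk, return_points=True)
    k = int(np.argmin(gaps))
    nearest_member = pts[order][0]
    # the physical insertion sits on the trunk surface: between the line's
    # closest-approach point and the trunk axis point it faces
    cluster.origin_estimate = 0.5 * (line_pts[k] + closest[k])
    cluster.extension_length = float(np.linalg.norm(nearest_member - line_pts[k]) + gaps[k])
    cluster.valid = cluster.extension_length <= d_ext
    if not cluster.valid:
        cluster.reason = f"extension {cluster.extension_length * 100:.1f} cm > d_ext"
    return cluster


def _merge_same_branch_clusters(valid: List[BranchOriginCluster],
                                tree: WeightedSkeletonGraph,
                                trunk_path: Sequence[int],
                                params: "SegmentationParams",
                                ) -> List[BranchOriginCluster]:
    """Merge valid clusters that landed on the same branch.

    Fragments of one origin region share vertices after augmentation, or
    their fitted lines aim at the same spot on the trunk; counting both would
    double-report the branch.  Distinct branches insert several origin
    separations apart, so origin-estimate proximity is a safe merge rule.
    """
    n = len(valid)
    if n <= 1:
        return valid
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    member_sets = [set(map(int, c.member_indices)) for c in valid]
    for i in range(n):
        for j in range(i + 1, n):
            same = bool(member_sets[i] & member_sets[j])
            if not same and valid[i].origin_estimate is not None \
                    and valid[j].origin_estimate is not None:
                same = np.linalg.norm(valid[i].origin_estimate
                                      - valid[j].origin_estimate) \
                    < max(0.04, params.epsilon)
            if same:
                parent[find(j)] = find(i)
    groups: Dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).update(member_sets[i])
    merged = []
    for members in groups.values():
        c = BranchOriginCluster(member_indices=np.asarray(sorted(members)))
        c = validate_origin_cluster(c, tree, trunk_path,
                                    params.extension_threshold)
        if c.valid:
            merged.append(c)
    merged.sort(key=lambda c: tree.vertices[c.member_indices][:, 2].mean())
    return merged


# ---------------------------------------------------------------------------
# branch growth
# ---------------------------------------------------------------------------

def _ba_weights_on_subset(tree: WeightedSkeletonGraph, vertex_ids: Sequence[int],
                          d_th: float, alpha: float) -> Dict[Tuple[int, int], float]:
    from scipy.spatial import cKDTree as _KD

    ids = np.asarray(sorted(vertex_ids))
    if len(ids) < 2:
        return {}
    kd = _KD(tree.vertices[ids])
    pairs = sorted({(int(ids[min(a, b)]), int(ids[max(a, b)]))
                    for a, b in kd.query_pairs(d_th)})
    if not pairs:
        return {}
    arr = np.asarray(pairs)
    lengths = np.linalg.norm(tree.vertices[arr[:, 0]] - tree.vertices[arr[:, 1]], axis=1)
    thick = 1.0 / tree.density[arr[:, 0]] + 1.0 / tree.density[arr[:, 1]]
    norm_t = float(thick.max()) or 1.0
    norm_l = float(lengths.max()) or 1.0
    vals = alpha * thick / norm_t + (1 - alpha) * lengths / norm_l
    return {tuple(p): float(v) for p, v in zip(pairs, vals)}


def grow_entire_branch(seed_cluster: BranchOriginCluster,
                       unassigned: Sequence[int],
                       tree: WeightedSkeletonGraph,
                       d_th: float, alpha: float = 0.5) -> BranchSegment:
    """Entire branch = optimal MST of the seed's component in the BA subgraph."""
    seed_ids = [int(i) for i in seed_cluster.member_indices]
    pool = sorted(set(unassigned) | set(seed_ids))
    edges = _ba_weights_on_subset(tree, pool, d_th, alpha)
    index = {v: i for i, v in enumerate(pool)}
    local_edges = {(index[u], index[v]): w for (u, v), w in edges.items()}
    forest, uf = minimum_spanning_edges(len(pool), local_edges)
    seed_roots = {uf.find(index[s]) for s in seed_ids}
    members = [v for v in pool if uf.find(index[v]) in seed_roots]
    branch_edges = {(pool[u], pool[v]): w for (u, v), w in forest.items()
                    if uf.find(u) in seed_roots}
    if len(members) == 1:
        warnings.warn("isolated branch seed: single-vertex branch")
    return BranchSegment(origin_cluster=seed_cluster, entire_branch=branch_edges,
                         vertices=members)


def extract_primary_branch(branch: BranchSegment, tree: WeightedSkeletonGraph,
                           alpha: float = 0.5) -> List[int]:
    """Primary path = maximal-weight path from the branch origin inside its MST."""
    if not branch.vertices:
        return []
    sub = WeightedSkeletonGraph(vertices=tree.vertices, density=tree.density,
                                edges=dict(branch.entire_branch), params=tree.params)
    weights = reweight_for_trunk(sub, alpha, edges=branch.entire_branch)
    origin = int(branch.origin_cluster.member_indices[0])
    weights.root_index = origin
    if not branch.entire_branch:
        return [origin]
    weights = path_weights_from_root(sub, weights)
    return identify_trunk(sub, weights)


# ---------------------------------------------------------------------------
# maximum direction matching
# ---------------------------------------------------------------------------

def _growth_angle(tree: WeightedSkeletonGraph, cluster: BranchOriginCluster,
                  target: np.ndarray) -> float:
    """Turn angle between the cluster's last grown segment and the step to target."""
    pts = tree.vertices[cluster.member_indices]
    d_to_target = np.linalg.norm(pts - target, axis=1)
    j = int(np.argmin(d_to_target))
    b_t = pts[j]
    if j > 0:
        b_prev = pts[j - 1]
    elif cluster.fitted_direction is not None:
        b_prev = b_t - cluster.fitted_direction * 1e-2
    else:
        b_prev = pts.mean(axis=0)
    v1 = b_t - b_prev
    v2 = target - b_t
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))))


def mdm_resolve(tree: WeightedSkeletonGraph,
                conflicted: Sequence[int],
                claiming_clusters: List[BranchOriginCluster],
                seed: int = 0) -> Dict[int, int]:
    """Assign multiply-claimed vertices to the branch that turns least.

    Conflicted vertices are spectral-clustered into k' groups (k' = number of
    claims); each group goes to the branch giving the minimum turn angle under
    a one-to-one matching.  Returns {vertex id: claiming-cluster position}.
    """
    ids = np.asarray(sorted(conflicted))
    k_prime = min(len(claiming_clusters), len(ids))
    if k_prime == 0:
        return {}
    pts = tree.vertices[ids]
    if k_prime == 1 or len(ids) < 2:
        groups = [np.arange(len(ids))]
    else:
        pd = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        bandwidth = np.median(pd[pd > 0]) if np.any(pd > 0) else 1.0
        affinity = np.exp(-(pd / bandwidth) ** 2)
        labels = SpectralClustering(n_clusters=k_prime, affinity="precomputed",
                                    random_state=seed).fit_predict(affinity)
        groups = [np.flatnonzero(labels == g) for g in sorted(set(labels))]
    angle = np.zeros((len(groups), len(claiming_clusters)))
    for gi, grp in enumerate(groups):
        centroid = pts[grp].mean(axis=0)
        for ci, cl in enumerate(claiming_clusters):
            angle[gi, ci] = _growth_angle(tree, cl, centroid)
    rows, cols = linear_sum_assignment(angle)
    assignment: Dict[int, int] = {}
    for gi, ci in zip(rows, cols):
        for local in groups[gi]:
            assignment[int(ids[local])] = int(ci)
    # groups beyond the number of branches fall back to the nearest branch
    for gi, grp in enumerate(groups):
        if gi not in set(rows):
            warnings.warn("MDM: more vertex groups than claiming branches; using nearest")
            centroid = pts[grp].mean(axis=0)
            dists = [np.linalg.norm(tree.vertices[c.member_indices] - centroid,
                                    axis=1).min() for c in claiming_clusters]
            ci = int(np.argmin(dists))
            for local in grp:
                assignment[int(ids[local])] = ci
    return assignment


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def segment_tree(tree: WeightedSkeletonGraph, original: PointCloud,
                 epsilon: float,
                 params: SegmentationParams | None = None) -> TreeTopology:
    """Full segmentation: trunk -> tube -> cluster -> validate -> grow -> MDM."""
    params = (params or SegmentationParams()).resolved(epsilon)
    component = getattr(tree, "component", list(range(tree.n_vertices)))
    weights = path_weights_from_root(tree, reweight_for_trunk(tree, params.alpha))
    trunk_path = identify_trunk(tree, weights)
    near = tube_prune(tree, trunk_path, params.tube_radius, component=component)
    clusters = cluster_branch_origins(tree, near, params.dbscan_eps, params.dbscan_min_pts)
    trunk_set_pre = set(trunk_path)
    adj = {v: set() for v in range(tree.n_vertices)}
    for (u, v) in tree.edges:
        adj[u].add(v)
        adj[v].add(u)
    for c in clusters:
        # a lone tube vertex carries no direction: pull in its immediate
        # non-trunk tree neighbors (within the clustering radius, so bridge
        # edges to other branches are not followed) to expose the heading
        extra = set()
        for m in c.member_indices:
            for nb in adj[int(m)]:
                if nb in trunk_set_pre:
                    continue
                if np.linalg.norm(tree.vertices[nb] - tree.vertices[int(m)]) \
                        <= max(params.dbscan_eps, 3.0 * params.epsilon):
                    extra.add(nb)
        c.member_indices = np.asarray(sorted(set(map(int, c.member_indices)) | extra))
    clusters = [validate_origin_cluster(c, tree, trunk_path, params.extension_threshold)
                for c in clusters]
    valid = _merge_same_branch_clusters([c for c in clusters if c.valid],
                                        tree, trunk_path, params)
    trunk_set = set(trunk_path)
    seed_owner: Dict[int, int] = {}
    for ci, c in enumerate(valid):
        for v in c.member_indices:
            seed_owner[int(v)] = ci
    d_th = tree.params.distance_threshold or 3 * epsilon
    segments: List[BranchSegment] = []
    claims: Dict[int, List[int]] = {}
    for ci, c in enumerate(valid):
        pool = [v for v in component
                if v not in trunk_set and seed_owner.get(v, ci) == ci]
        seg = grow_entire_branch(c, pool, tree, d_th, params.alpha)
        segments.append(seg)
        for v in seg.vertices:
            claims.setdefault(v, []).append(ci)
    conflicted = sorted(v for v, owners in claims.items() if len(owners) > 1)
    if conflicted:
        owners_sets = sorted({tuple(claims[v]) for v in conflicted})
        for owner_tuple in owners_sets:
            group = [v for v in conflicted if tuple(claims[v]) == owner_tuple]
            resolved = mdm_resolve(tree, group, [valid[c] for c in owner_tuple],
                                   seed=params.seed)
            for v, local_ci in resolved.items():
                claims[v] = [owner_tuple[local_ci]]
        # rebuild branch MSTs on the now-disjoint assignments
        for ci, c in enumerate(valid):
            mine = [v for v, owners in claims.items() if owners == [ci]]
            segments[ci] = grow_entire_branch(c, mine, tree, d_th, params.alpha)
    # rescue: subtrees hanging off the trunk that no cluster claimed are
    # branches whose origin region contracted into the trunk filament (the
    # junction shadow); their MST attachment to the trunk is the evidence
    # the tube test could not see
    claimed = set(claims.keys())
    for u in trunk_path:
        for v0 in sorted(adj[u]):
            if v0 in trunk_set or v0 in claimed:
                continue
            comp, stack = set(), [v0]
            while stack:
                x = stack.pop()
                if x in comp or x in trunk_set:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp - trunk_set)
            if len(comp) < 2 or comp & claimed:
                continue
            trunk_pts = tree.vertices[list(trunk_path)]
            order = sorted(comp, key=lambda x: float(
                _point_to_polyline_distance(tree.vertices[x], trunk_pts)[0]))
            c = BranchOriginCluster(member_indices=np.asarray(order[:4]))
            c = validate_origin_cluster(c, tree, trunk_path, np.inf)
            c.reason = "trunk-attached subtree"
            seg = grow_entire_branch(c, sorted(comp), tree, d_th, params.alpha)
            segments.append(seg)
            claimed |= comp
    for seg in segments:
        seg.primary_path = extract_primary_branch(seg, tree, params.alpha)
    segments.sort(key=lambda s: tree.vertices[s.origin_cluster.member_indices][:, 2].mean())
    return TreeTopology(trunk_path=trunk_path, branches=segments, skeleton=tree)
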
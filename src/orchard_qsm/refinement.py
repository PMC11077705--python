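"""Cylinder-prior refinement of trunk and branch skeletons.

Each coarse skeleton vertex spawns a local region of original points (radius
R'), sliced into thin cross-section slabs along the local axis.  Every slab
center is optimized under the cylindrical prior

    v* = argmin_v  sum_i |v - x_i|  +  lambda * Var_i(|v - x_i|)

whose first term is the L1 geometric-median (centeredness) constraint and
whose second term is the equidistance constraint pulling v onto the axis of a
cylindrical point set.  Centers are filtered by seeded RANSAC line fits,
first within each local region, then semi-globally over sliding windows of
K_1 consecutive centers; the surviving centers are resampled with a cubic
smoothing spline at M equal arc-length steps, and each resampled point gets
the mean radius of its N nearest cross sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.spatial import cKDTree

from .pointcloud_io import PointCloud

__all__ = [
    "CrossSection",
    "RefinementParams",
    "RefinedAxis",
    "cpc_optimize",
    "slice_cross_sections",
    "cross_section_radius",
    "local_ransac_filter",
    "semiglobal_ransac_filter",
    "spline_resample",
    "assign_radii",
    "refine_axis",
]


@dataclass
class CrossSection:
    members: np.ndarray                 # (m, 3) original points of the slab
    slab_axis: np.ndarray               # unit direction
    slab_depth: float
    center: Optional[np.ndarray] = None
    radius: float = 0.0
    converged: bool = True


@dataclass
class RefinementParams:
    region_radius: float = 0.05     # R' (m)
    slab_depth: float = 0.01        # (m); must stay well below typical radii... of R'
    lam: float = 1.0                # lambda of the variance penalty
    ransac_window: int = 10         # K_1
    spline_samples: Optional[int] = None  # M; None -> ceil(length / 2 cm)
    radius_neighbors: int = 5       # N
    ransac_inlier_tol: float = 0.01  # (m)
    seed: int = 0
    max_iter: int = 200
    tol: float = 1e-8


@dataclass
class RefinedAxis:
    centers: np.ndarray             # (M, 3)
    radii: np.ndarray               # (M,)
    arc_length: float
    source: str = "trunk"
    branch_id: Optional[int] = None
    flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# CPC center optimization
# ---------------------------------------------------------------------------

def _cpc_objective_grad(v: np.ndarray, x: np.ndarray, lam: float):
    diff = v - x
    u = np.linalg.norm(diff, axis=1)
    safe = np.maximum(u, 1e-12)
    e = diff / safe[:, None]
    obj = u.sum() + lam * u.var()
    grad = e.sum(axis=0) + lam * (2.0 / len(x)) * ((u - u.mean()) @ e)
    return obj, grad


def cpc_optimize(members: np.ndarray, lam: float = 1.0,
                 tol: float = 1e-8, max_iter: int = 200) -> Tuple[np.ndarray, bool]:
    """Minimize the cylinder-prior objective; deterministic.

    Initialized at the coordinate-wise median and driven by gradient descent
    with backtracking line search.  With lam=0 this reduces to the geometric
    median.  Returns (center, converged).
    """
    x = np.atleast_2d(np.asarray(members, dtype=np.float64))
    if len(x) == 0:
        raise ValueError("empty cross section")
    if len(x) == 1:
        return x[0].copy(), True
    v = np.median(x, axis=0)
    obj, grad = _cpc_objective_grad(v, x, lam)
    step = 0.1 * float(np.linalg.norm(x - v, axis=1).mean() + 1e-12)
    for _ in range(max_iter):
        gnorm = np.linalg.norm(grad)
        if gnorm < tol * max(1.0, abs(obj)):
            return v, True
        direction = -grad / gnorm
        improved = False
        s = step
        for _ in range(40):
            cand = v + s * direction
            cand_obj, cand_grad = _cpc_objective_grad(cand, x, lam)
            if cand_obj < obj - 1e-15:
                v, obj, grad = cand, cand_obj, cand_grad
                step = 1.5 * s
                improved = True
                break
            s *= 0.5
        if not improved:
            return v, True  # no descent direction at line-search floor
    return v, False


# ---------------------------------------------------------------------------
# slicing + per-slab radius
# ---------------------------------------------------------------------------

def slice_cross_sections(skeleton_vertex: np.ndarray, local_axis: np.ndarray,
                         original: PointCloud, region_radius: float,
                         slab_depth: float,
                         kd: Optional[cKDTree] = None,
                         min_points_per_slab: int = 24) -> List[CrossSection]:
    """Partition the R'-ball of original points into consecutive axial slabs.

    The nominal slab depth thickens adaptively on sparse structures so every
    slab keeps at least ``min_points_per_slab`` points on average: a center
    optimized over a handful of points collapses onto them and the radius
    estimate with it.  (Thin slabs relative to the radius remain the ideal;
    sparse surfaces simply cannot afford them.)
    """
    axis = np.asarray(local_axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    kd = kd or cKDTree(original.coords)
    idx = kd.query_ball_point(np.asarray(skeleton_vertex), region_radius)
    if not idx:
        return []
    pts = original.coords[sorted(idx)]
    t = (pts - skeleton_vertex) @ axis
    t_range = float(t.max() - t.min())
    if t_range <= 0:
        return [CrossSection(members=pts, slab_axis=axis, slab_depth=slab_depth)]
    n_by_depth = max(1, int(np.floor(t_range / slab_depth)))
    n_by_count = max(1, len(pts) // min_points_per_slab)
    n_slabs = min(n_by_depth, n_by_count)
    depth = t_range / n_slabs
    bins = np.minimum(((t - t.min()) / depth).astype(np.int64), n_slabs - 1)
    sections = []
    for b in sorted(set(bins)):
        members = pts[bins == b]
        sections.append(CrossSection(members=members, slab_axis=axis,
                                     slab_depth=depth))
    return sections


def cross_section_radius(section: CrossSection) -> float:
    """Mean in-plane (slab-projected) distance from the optimized center."""
    if section.center is None:
        raise ValueError("center not computed")
    diff = section.members - section.center
    in_plane = diff - np.outer(diff @ section.slab_axis, section.slab_axis)
    section.radius = float(np.linalg.norm(in_plane, axis=1).mean())
    return section.radius


# ---------------------------------------------------------------------------
# RANSAC center correction
# ---------------------------------------------------------------------------

def _ransac_line(points: np.ndarray, inlier_tol: float, rng: np.random.Generator,
                 n_trials: int = 64) -> np.ndarray:
    """Seeded RANSAC 3D line; returns boolean inlier mask (best = most inliers)."""
    m = len(points)
    best_mask = np.ones(m, dtype=bool)
    best_count = -1
    for _ in range(n_trials):
        i, j = rng.choice(m, size=2, replace=False)
        if np.allclose(points[i], points[j]):
            continue
        d = points[j] - points[i]
        d = d / np.linalg.norm(d)
        diff = points - points[i]
        dist = np.linalg.norm(diff - np.outer(diff @ d, d), axis=1)
        mask = dist <= inlier_tol
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask = count, mask
    return best_mask


def local_ransac_filter(centers: np.ndarray, inlier_tol: float = 0.01,
                        seed: int = 0) -> np.ndarray:
    """Inlier mask of a seeded RANSAC line fit within one local region."""
    centers = np.atleast_2d(centers)
    if len(centers) < 3:
        return np.ones(len(centers), dtype=bool)
    rng = np.random.default_rng(seed)
    return _ransac_line(centers, inlier_tol, rng)


def semiglobal_ransac_filter(centers: np.ndarray, K_1: int = 10,
                             inlier_tol: float = 0.01, seed: int = 0) -> np.ndarray:
    """Sliding-window RANSAC over every K_1 consecutive centers (stride K_1//2).

    A center is an outlier only if every window containing it calls it one,
    which keeps sparse-but-consistent stretches of the axis.
    """
    centers = np.atleast_2d(centers)
    m = len(centers)
    if m < 3:
        return np.ones(m, dtype=bool)
    k = min(K_1, m)
    stride = max(1, k // 2)
    rng = np.random.default_rng(seed)
    seen = np.zeros(m, dtype=bool)
    inlier_any = np.zeros(m, dtype=bool)
    start = 0
    while True:
        stop = min(start + k, m)
        window = np.arange(max(0, stop - k), stop)
        mask = _ransac_line(centers[window], inlier_tol, rng)
        seen[window] = True
        inlier_any[window] |= mask
        if stop == m:
            break
        start += stride
    inlier_any[~seen] = True
    return inlier_any


# ---------------------------------------------------------------------------
# spline resampling + radii
# ---------------------------------------------------------------------------

def _dedupe_ordered(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > tol:
            keep.append(i)
    return points[keep]


def spline_resample(inlier_centers: np.ndarray, M: int,
                    flags: Optional[List[str]] = None) -> np.ndarray:
    """Cubic smoothing spline through ordered centers, sampled at M equal
    arc-length steps (GCV-chosen smoothing; endpoints preserved)."""
    pts = _dedupe_ordered(np.atleast_2d(np.asarray(inlier_centers, dtype=np.float64)))
    if M < 2:
        raise ValueError("M must be >= 2")
    if len(pts) < 2:
        raise ValueError("need at least 2 distinct centers")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if len(pts) < 4:
        if flags is not None:
            flags.append("spline fallback: linear interpolation (<4 inliers)")
        splines = [CubicSpline(chord, pts[:, d], bc_type="natural") if len(pts) > 2
                   else (lambda c=chord, y=pts[:, d]: None) for d in range(3)]
        if len(pts) == 2:
            s = np.linspace(0, chord[-1], M)
            return pts[0] + np.outer(s / chord[-1], pts[1] - pts[0])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            splines = [make_smoothing_spline(chord, pts[:, d]) for d in range(3)]
    # dense arc-length table along the smoothing spline
    dense_t = np.linspace(0.0, chord[-1], max(50 * M, 1000))
    dense = np.column_stack([sp(dense_t) for sp in splines])
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], M)
    t_of_s = np.interp(targets, arc, dense_t)
    return np.column_stack([sp(t_of_s) for sp in splines])


def assign_radii(axis_points: np.ndarray, section_centers: np.ndarray,
                 section_radii: np.ndarray, N: int = 5,
                 flags: Optional[List[str]] = None) -> np.ndarray:
    """Radius at each resampled point = mean radius of the N nearest sections."""
    section_centers = np.atleast_2d(section_centers)
    n = min(N, len(section_centers))
    if n < N and flags is not None:
        flags.append(f"radius pooling used all {n} sections (< N={N})")
    kd = cKDTree(section_centers)
    _, nbrs = kd.query(np.atleast_2d(axis_points), k=n)
    nbrs = nbrs.reshape(len(axis_points), n)
    return np.asarray(section_radii)[nbrs].mean(axis=1)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def refine_axis(path_vertices: np.ndarray, original: PointCloud,
                params: RefinementParams | None = None,
                source: str = "trunk", branch_id: Optional[int] = None,
                kd: Optional[cKDTree] = None,
                anchor_ends: bool = False) -> RefinedAxis:
    """Slice -> CPC -> local RANSAC -> semi-global RANSAC -> spline -> radii.

    With ``anchor_ends`` the exact path endpoints are kept as axis centers, so
    the refined axis spans the full structure instead of stopping half a slab
    short at each extremity (used for the trunk, whose z extent is a trait).
    """
    params = params or RefinementParams()
    path = np.atleast_2d(np.asarray(path_vertices, dtype=np.float64))
    if len(path) < 2:
        raise ValueError("refine_axis needs a path of >= 2 vertices")
    kd = kd or cKDTree(original.coords)
    flags: List[str] = []
    all_centers, all_radii, all_order = [], [], []
    for vi, vertex in enumerate(path):
        lo, hi = max(0, vi - 1), min(len(path) - 1, vi + 1)
        axis = path[hi] - path[lo]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            continue
        axis = axis / norm
        sections = slice_cross_sections(vertex, axis, original,
                                        params.region_radius, params.slab_depth, kd=kd)
        centers, radii, order = [], [], []
        for section in sections:
            center, ok = cpc_optimize(section.members, params.lam,
                                      params.tol, params.max_iter)
            section.center = center
            if not ok:
                flags.append(f"CPC non-convergence near vertex {vi}")
            centers.append(center)
            radii.append(cross_section_radius(section))
            order.append(vi + float((center - vertex) @ axis) / (2 * params.region_radius))
        if not centers:
            continue
        centers = np.asarray(centers)
        mask = local_ransac_filter(centers, params.ransac_inlier_tol,
                                   seed=params.seed + vi)
        all_centers.extend(centers[mask])
        all_radii.extend(np.asarray(radii)[mask])
        all_order.extend(np.asarray(order)[mask])
    if len(all_centers) < 2:
        raise ValueError("refinement produced fewer than 2 centers")
    order_ix = np.argsort(all_order, kind="stable")
    centers = np.asarray(all_centers)[order_ix]
    radii = np.asarray(all_radii)[order_ix]
    mask = semiglobal_ransac_filter(centers, params.ransac_window,
                                    params.ransac_inlier_tol, seed=params.seed)
    centers, radii = centers[mask], radii[mask]
    if anchor_ends:
        centers = np.vstack([path[0], centers, path[-1]])
        radii = np.concatenate([[radii[0]], radii, [radii[-1]]])
    length = float(np.linalg.norm(np.diff(centers, axis=0), axis=1).sum())
    M = params.spline_samples or max(2, int(np.ceil(length / 0.02)))
    resampled = spline_resample(centers, M, flags=flags)
    out_radii = assign_radii(resampled, centers, radii, params.radius_neighbors, flags=flags)
    arc = float(np.linalg.norm(np.diff(resampled, axis=0), axis=1).sum())
    return RefinedAxis(centers=resampled, radii=out_radii, arc_length=arc,
                       source=source, branch_id=branch_id, flags=flags)
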
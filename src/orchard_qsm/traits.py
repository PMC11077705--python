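"""Architectural trait extraction from refined axes and the original cloud.

Tree level: height (refined-trunk z extent plus a constant offset for the
rootstock cover removed during preprocessing) and trunk diameter (robust
ellipse fit of the bottom cross-section slice).  Branch level: diameter (twice
the mean of the first K_3 refined radii out from the trunk) and inclination
angle (mean 3D angle between the first K_2 branch vectors and a RANSAC line
fit of the local trunk segment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from sklearn.cluster import DBSCAN

from .pointcloud_io import PointCloud
from .refinement import RefinedAxis

__all__ = [
    "TraitConfig",
    "BranchTraits",
    "TraitRecord",
    "tree_height",
    "trunk_bottom_points",
    "fit_ellipse_robust",
    "trunk_diameter",
    "branch_inclination_angle",
    "branch_diameter",
    "extract_traits",
]


@dataclass
class TraitConfig:
    cover_offset: float = 60.0      # cm added to the refined-trunk z extent
    bottom_slice_height: float = 0.10   # C_z (m) above the lowest point
    angle_vectors: int = 5          # K_2
    diameter_points: int = 5        # K_3
    dbscan_eps: float = 0.03
    dbscan_min_pts: int = 5
    seed: int = 0


@dataclass
class BranchTraits:
    branch_id: int
    diameter_mm: float
    inclination_deg: float
    flags: List[str] = field(default_factory=list)


@dataclass
class TraitRecord:
    tree_height_cm: float = np.nan
    trunk_diameter_mm: float = np.nan
    branch_count: int = 0
    branches: List[BranchTraits] = field(default_factory=list)
    flags: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict:
        return {
            "tree_height_cm": self.tree_height_cm,
            "trunk_diameter_mm": self.trunk_diameter_mm,
            "branch_count": self.branch_count,
            "branches": [
                {"branch_id": b.branch_id, "diameter_mm": b.diameter_mm,
                 "inclination_deg": b.inclination_deg, "flags": b.flags}
                for b in self.branches
            ],
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# tree level
# ---------------------------------------------------------------------------

def tree_height(trunk: RefinedAxis, cover_offset: float = 60.0) -> float:
    """Height in cm: refined-trunk z extent plus the removed-cover offset."""
    z = trunk.centers[:, 2]
    return float((z.max() - z.min()) * 100.0 + cover_offset)


def trunk_bottom_points(cloud: PointCloud, C_z: float = 0.10,
                        dbscan_eps: float = 0.03, dbscan_min_pts: int = 5,
                        ) -> np.ndarray:
    """xy projection of the largest DBSCAN cluster in the bottom z-slice."""
    if cloud.n == 0:
        raise ValueError("empty cloud")
    z_min = cloud.coords[:, 2].min()
    sel = cloud.coords[cloud.coords[:, 2] < z_min + C_z]
    if len(sel) == 0:
        raise ValueError("empty bottom slice")
    labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_pts).fit_predict(sel)
    valid = labels[labels >= 0]
    if len(valid) == 0:
        return sel[:, :2]
    counts = np.bincount(valid)
    return sel[labels == int(np.argmax(counts)), :2]


def _direct_ellipse_fit(points: np.ndarray) -> np.ndarray:
    """Direct least-squares conic fit with the 4ac - b^2 = 1 constraint."""
    x, y = points[:, 0], points[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    t = -np.linalg.solve(s3, s2.T)
    m = s1 + s2 @ t
    c_inv = np.array([[0, 0, 0.5], [0, -1, 0], [0.5, 0, 0]])
    vals, vecs = np.linalg.eig(c_inv @ m)
    cond = 4 * vecs[0] * vecs[2] - vecs[1] ** 2
    good = np.flatnonzero((cond > 0) & np.isfinite(vals))
    if len(good) == 0:
        raise ValueError("degenerate conic")
    a1 = np.real(vecs[:, good[np.argmax(np.real(vals[good]))]])
    return np.concatenate([a1, t @ a1])


def _conic_to_ellipse(coef: np.ndarray):
    a, b, c, d, e, f = coef
    den = b * b - 4 * a * c
    if den >= 0:
        raise ValueError("degenerate conic")
    cx = (2 * c * d - b * e) / den
    cy = (2 * a * e - b * d) / den
    theta = 0.5 * np.arctan2(b, a - c)
    mu = 1.0 / (a * cx * cx + b * cx * cy + c * cy * cy - f)
    m = mu * np.array([[a, b / 2], [b / 2, c]])
    evals = np.linalg.eigvalsh(m)
    if np.any(evals <= 0):
        raise ValueError("degenerate conic")
    axes = 1.0 / np.sqrt(evals)          # descending: semi-major first
    return float(axes.max()), float(axes.min()), np.array([cx, cy]), float(theta)


def fit_ellipse_robust(points2d: np.ndarray, seed: int = 0,
                       inlier_tol: float = 0.005, n_trials: int = 100):
    """Seeded RANSAC over 5-point direct ellipse fits, refit on inliers.

    Returns (semi_major, semi_minor, center, orientation) in input units.
    """
    pts = np.atleast_2d(np.asarray(points2d, dtype=np.float64))
    if len(pts) < 5:
        raise ValueError("ellipse fit needs >= 5 points")
    rng = np.random.default_rng(seed)
    best_mask, best_count = None, -1
    for _ in range(n_trials):
        sample = rng.choice(len(pts), size=5, replace=False)
        try:
            coef = _direct_ellipse_fit(pts[sample])
            a, b, center, theta = _conic_to_ellipse(coef)
        except (ValueError, np.linalg.LinAlgError):
            continue
        resid = _ellipse_residual(pts, a, b, center, theta)
        mask = resid <= inlier_tol
        if mask.sum() > best_count:
            best_count, best_mask = int(mask.sum()), mask
    if best_mask is None or best_count < 5:
        best_mask = np.ones(len(pts), dtype=bool)
    coef = _direct_ellipse_fit(pts[best_mask])
    return _conic_to_ellipse(coef)


def _ellipse_residual(pts, a, b, center, theta) -> np.ndarray:
    """Approximate point-to-ellipse distance via radial scaling."""
    rot = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
    local = (pts - center) @ rot.T
    r = np.linalg.norm(local, axis=1)
    phi = np.arctan2(local[:, 1], local[:, 0])
    r_ell = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    return np.abs(r - r_ell)


def trunk_diameter(cloud: PointCloud, config: TraitConfig | None = None) -> float:
    """Trunk diameter in mm: a + b of the robust ellipse fit of the bottom slice."""
    config = config or TraitConfig()
    pts2d = trunk_bottom_points(cloud, config.bottom_slice_height,
                                config.dbscan_eps, config.dbscan_min_pts)
    a, b, _, _ = fit_ellipse_robust(pts2d, seed=config.seed)
    return float((a + b) * 1000.0)


# ---------------------------------------------------------------------------
# branch level
# ---------------------------------------------------------------------------

def _ransac_line_direction(points: np.ndarray, rng: np.random.Generator,
                           inlier_tol: float = 0.01, n_trials: int = 64) -> np.ndarray:
    """Best-line direction by seeded RANSAC; refit on inliers by SVD."""
    if len(points) == 2:
        d = points[1] - points[0]
        return d / np.linalg.norm(d)
    best_mask, best_count = np.ones(len(points), dtype=bool), -1
    for _ in range(n_trials):
        i, j = rng.choice(len(points), size=2, replace=False)
        if np.allclose(points[i], points[j]):
            continue
        d = points[j] - points[i]
        d = d / np.linalg.norm(d)
        diff = points - points[i]
        dist = np.linalg.norm(diff - np.outer(diff @ d, d), axis=1)
        mask = dist <= inlier_tol
        if mask.sum() > best_count:
            best_count, best_mask = int(mask.sum()), mask
    inl = points[best_mask]
    _, _, vt = np.linalg.svd(inl - inl.mean(axis=0), full_matrices=False)
    return vt[0] / np.linalg.norm(vt[0])


def branch_inclination_angle(branch: RefinedAxis, trunk: RefinedAxis,
                             K_2: int = 5, seed: int = 0,
                             flags: Optional[List[str]] = None) -> float:
    """Mean 3D angle (degrees) between the first K_2 branch vectors and the
    local trunk axis, the trunk vector oriented upward."""
    centers = branch.centers
    if len(centers) < 2:
        raise ValueError("branch axis too short for angle computation")
    # local trunk segment: refined trunk centers within the branch z-span
    z = trunk.centers[:, 2]
    spacing = max(np.abs(np.diff(z)).max(), 1e-6) if len(z) > 1 else 0.05
    z_lo, z_hi = centers[:, 2].min() - spacing, centers[:, 2].max() + spacing
    seg = trunk.centers[(z >= z_lo) & (z <= z_hi)]
    if len(seg) < 2:
        order = np.argsort(np.abs(z - centers[0, 2]))[:max(2, K_2)]
        seg = trunk.centers[np.sort(order)]
        if flags is not None:
            flags.append("short local trunk segment; used nearest trunk centers")
    rng = np.random.default_rng(seed)
    v_t = _ransac_line_direction(seg, rng)
    if v_t[2] < 0:
        v_t = -v_t
    n_vec = min(K_2, len(centers) - 1)
    if n_vec < K_2 and flags is not None:
        flags.append(f"only {n_vec} branch vectors available (< K_2={K_2})")
    vecs = np.diff(centers[: n_vec + 1], axis=0)
    norms = np.linalg.norm(vecs, axis=1)
    vecs = vecs[norms > 1e-12]
    norms = norms[norms > 1e-12]
    cosines = np.clip(vecs @ v_t / norms, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosines)).mean())


def branch_diameter(branch: RefinedAxis, K_3: int = 5) -> float:
    """Diameter in mm: 2x mean of the first K_3 refined radii (trunk outward)."""
    radii = branch.radii[: max(1, K_3)]
    return float(2.0 * radii.mean() * 1000.0)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def extract_traits(trunk: RefinedAxis, branches: List[RefinedAxis],
                   cloud: PointCloud, config: TraitConfig | None = None,
                   ) -> TraitRecord:
    """Assemble the tree- and branch-level trait record; failures become flags."""
    config = config or TraitConfig()
    record = TraitRecord()
    try:
        record.tree_height_cm = tree_height(trunk, config.cover_offset)
    except Exception as exc:
        record.flags.append(f"tree height unavailable: {exc}")
    try:
        record.trunk_diameter_mm = trunk_diameter(cloud, config)
    except Exception as exc:
        record.flags.append(f"trunk diameter unavailable: {exc}")
    record.branch_count = len(branches)
    for i, axis in enumerate(branches):
        flags: List[str] = []
        bid = axis.branch_id if axis.branch_id is not None else i
        try:
            diam = branch_diameter(axis, config.diameter_points)
            angle = branch_inclination_angle(axis, trunk, config.angle_vectors,
                                             seed=config.seed + i, flags=flags)
            record.branches.append(BranchTraits(branch_id=bid, diameter_mm=diam,
                                                inclination_deg=angle, flags=flags))
        except Exception as exc:
            record.flags.append(f"branch {bid} traits unavailable: {exc}")
    return record
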
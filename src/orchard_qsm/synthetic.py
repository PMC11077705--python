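"""Synthetic orchard trees with known architecture.

Trunk and primary branches are modeled as tapered, optionally curved
generalized cylinders; surface points are sampled at a target areal density
with isotropic Gaussian sensor noise.  Every point carries a structure label
(0 = trunk, i = branch i), and the generator records the true trait values a
perfect pipeline should recover, so segmentation recall and trait errors can
be scored without field data.  Degradation operators emulate the dominant
TLS data-quality defects: occlusion sectors, junction gaps and stray
outliers.

Ranges of the default random specs follow trellised high-density apple
plantings: heights 2.4-3.9 m, trunk diameters 42-68 mm, 6-15 primary
branches per tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pointcloud_io import PointCloud
from .traits import BranchTraits, TraitRecord

__all__ = [
    "BranchSpec",
    "SyntheticTreeSpec",
    "GroundTruth",
    "Gap",
    "EvalReport",
    "generate_tree",
    "degrade",
    "evaluate",
    "random_tree_spec",
    "suite_specs",
]


@dataclass
class BranchSpec:
    insertion_height: float      # m above trunk base
    azimuth: float               # deg around the trunk axis
    inclination: float           # deg from the (leaning) trunk axis
    diameter: float              # mm at the junction
    length: float                # m
    curvature: float = 0.0       # 1/m, gentle downward droop
    taper_fraction: float = 0.4  # tip diameter as a fraction of base diameter


@dataclass
class SyntheticTreeSpec:
    height: float = 3.2                  # m, trunk extent
    trunk_diameter_base: float = 55.0    # mm
    trunk_taper: float = 8.0             # mm per m of height
    trunk_lean: float = 3.0              # deg from vertical
    branches: List[BranchSpec] = field(default_factory=list)
    surface_density: float = 5e4         # points / m^2 on the trunk
    noise_sigma: float = 2.0             # mm, isotropic
    # TLS surfaces return more pulses on thick structures; per-structure areal
    # density scales as (diameter / trunk diameter) ** exponent
    density_thickness_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1.5 <= self.height <= 4.5:
            raise ValueError("height outside plausible orchard range")
        if not 30.0 <= self.trunk_diameter_base <= 80.0:
            raise ValueError("trunk diameter outside plausible range")

    @property
    def n_branches(self) -> int:
        return len(self.branches)


@dataclass
class GroundTruth:
    labels: np.ndarray                   # per-point: 0 trunk, i branch i
    traits: TraitRecord
    trunk_polyline: np.ndarray
    branch_polylines: Dict[int, np.ndarray]
    branch_origins: Dict[int, np.ndarray]
    spec: SyntheticTreeSpec = None


@dataclass
class Gap:
    """A removal window: angular sector and/or axial range on one structure."""

    target: int = 0                      # 0 = trunk, i = branch i
    axial_range: Optional[Tuple[float, float]] = None    # m along the axis
    angular_range: Optional[Tuple[float, float]] = None  # deg (start, extent)


@dataclass
class EvalReport:
    traits: Dict[str, Dict[str, float]] = field(default_factory=dict)
    branch_tp: int = 0
    branch_fp: int = 0
    n_true_branches: int = 0
    flags: List[str] = field(default_factory=list)

    @property
    def tp_rate(self) -> float:
        return self.branch_tp / self.n_true_branches if self.n_true_branches else np.nan

    @property
    def fp_rate(self) -> float:
        return self.branch_fp / self.n_true_branches if self.n_true_branches else np.nan


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _orthonormal_frame(direction: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = np.cross(d, helper)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(d, n1)
    return n1, n2


def _sample_generalized_cylinder(axis_fn, radius_fn, s_max: float, density: float,
                                 rng: np.random.Generator, sigma_m: float,
                                 n_stations: int = 400):
    """Area-weighted surface sampling of a generalized cylinder.

    ``axis_fn(s)`` and ``radius_fn(s)`` give centerline and radius at arc
    parameter s in [0, s_max].  Returns (points, s_values, angles).
    """
    s_grid = np.linspace(0.0, s_max, n_stations)
    r_grid = np.maximum(radius_fn(s_grid), 1e-4)
    area = 2.0 * np.pi * np.trapezoid(r_grid, s_grid)
    n_points = max(1, int(round(area * density)))
    # inverse-CDF sample of s with weight proportional to local radius
    cdf = np.concatenate([[0.0], np.cumsum((r_grid[1:] + r_grid[:-1]) / 2 * np.diff(s_grid))])
    cdf /= cdf[-1]
    u = rng.random(n_points)
    s = np.interp(u, cdf, s_grid)
    theta = rng.uniform(0.0, 2.0 * np.pi, n_points)
    centers = axis_fn(s)
    radii = radius_fn(s)
    # local frame from the axis tangent (finite difference)
    eps = max(s_max * 1e-4, 1e-6)
    tangent = axis_fn(np.minimum(s + eps, s_max)) - axis_fn(np.maximum(s - eps, 0.0))
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    helper = np.where(np.abs(tangent[:, [0]]) < 0.9,
                      np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
    n1 = np.cross(tangent, helper)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangent, n1)
    pts = centers + radii[:, None] * (np.cos(theta)[:, None] * n1 +
                                      np.sin(theta)[:, None] * n2)
    pts = pts + rng.normal(0.0, sigma_m, size=pts.shape)
    return pts, s, np.degrees(theta) % 360.0


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def _trunk_model(spec: SyntheticTreeSpec, rng: np.random.Generator):
    lean = np.radians(spec.trunk_lean)
    lean_az = rng.uniform(0.0, 2.0 * np.pi)
    direction = np.array([np.sin(lean) * np.cos(lean_az),
                          np.sin(lean) * np.sin(lean_az),
                          np.cos(lean)])

    def axis_fn(s):
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        return s[:, None] * direction

    def radius_fn(s):
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        d_mm = spec.trunk_diameter_base - spec.trunk_taper * s
        return np.maximum(d_mm, 5.0) / 2000.0

    s_max = spec.height / direction[2]   # arc length reaching the spec height
    return axis_fn, radius_fn, direction, s_max


def _branch_model(bspec: BranchSpec, trunk_axis_fn, trunk_dir: np.ndarray):
    origin = trunk_axis_fn(bspec.insertion_height / trunk_dir[2])[0]
    n1, n2 = _orthonormal_frame(trunk_dir)
    az = np.radians(bspec.azimuth)
    radial = np.cos(az) * n1 + np.sin(az) * n2
    incl = np.radians(bspec.inclination)
    direction = np.cos(incl) * trunk_dir + np.sin(incl) * radial
    direction /= np.linalg.norm(direction)
    droop = np.array([0.0, 0.0, -1.0])
    droop = droop - (droop @ direction) * direction
    droop_norm = np.linalg.norm(droop)
    droop = droop / droop_norm if droop_norm > 1e-9 else np.zeros(3)

    def axis_fn(s):
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        return origin + s[:, None] * direction + \
            (0.5 * bspec.curvature * s ** 2)[:, None] * droop

    def radius_fn(s):
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        frac = 1.0 - (1.0 - bspec.taper_fraction) * np.clip(s / bspec.length, 0, 1)
        return bspec.diameter * frac / 2000.0

    return axis_fn, radius_fn, origin, direction


def generate_tree(spec: SyntheticTreeSpec) -> Tuple[PointCloud, GroundTruth]:
    """Sample a labeled point cloud and its ground truth from a tree spec."""
    rng = np.random.default_rng(spec.seed)
    sigma_m = spec.noise_sigma / 1000.0
    trunk_axis, trunk_radius, trunk_dir, s_max = _trunk_model(spec, rng)

    # reject branch layouts whose origins collide
    origins = []
    models = []
    for i, b in enumerate(spec.branches, start=1):
        axis_fn, radius_fn, origin, direction = _branch_model(b, trunk_axis, trunk_dir)
        for prev in origins:
            if np.linalg.norm(origin - prev) < 0.04:
                raise ValueError(f"branch {i} origin overlaps an earlier branch")
        origins.append(origin)
        models.append((axis_fn, radius_fn, origin, direction))

    pts_list, lab_list = [], []
    trunk_pts, _, _ = _sample_generalized_cylinder(
        trunk_axis, trunk_radius, s_max, spec.surface_density, rng, sigma_m)
    pts_list.append(trunk_pts)
    lab_list.append(np.zeros(len(trunk_pts), dtype=np.int64))

    truth_branches: List[BranchTraits] = []
    branch_polylines: Dict[int, np.ndarray] = {}
    branch_origins: Dict[int, np.ndarray] = {}
    for i, (b, (axis_fn, radius_fn, origin, direction)) in enumerate(
            zip(spec.branches, models), start=1):
        r_trunk = float(trunk_radius(b.insertion_height)[0])
        density = spec.surface_density * (
            b.diameter / spec.trunk_diameter_base) ** spec.density_thickness_exponent
        pts, s, _ = _sample_generalized_cylinder(
            axis_fn, radius_fn, b.length, density, rng, sigma_m)
        keep = s > r_trunk          # do not sample inside the trunk
        pts_list.append(pts[keep])
        lab_list.append(np.full(int(keep.sum()), i, dtype=np.int64))
        s_line = np.linspace(0.0, b.length, 50)
        branch_polylines[i] = axis_fn(s_line)
        branch_origins[i] = origin + r_trunk * direction
        # field-protocol truth: diameter 5 cm out from the junction surface
        s_meas = min(r_trunk + 0.05, b.length)
        truth_branches.append(BranchTraits(
            branch_id=i,
            diameter_mm=float(2000.0 * radius_fn(s_meas)[0]),
            inclination_deg=b.inclination,
        ))

    coords = np.vstack(pts_list)
    labels = np.concatenate(lab_list)
    traits = TraitRecord(
        tree_height_cm=spec.height * 100.0 + 60.0,
        # ellipse fit pools the bottom slice; truth taken at its mid-height
        trunk_diameter_mm=spec.trunk_diameter_base - spec.trunk_taper * 0.05,
        branch_count=spec.n_branches,
        branches=truth_branches,
    )
    s_line = np.linspace(0.0, s_max, 100)
    truth = GroundTruth(labels=labels, traits=traits,
                        trunk_polyline=trunk_axis(s_line),
                        branch_polylines=branch_polylines,
                        branch_origins=branch_origins, spec=spec)
    return PointCloud(coords), truth


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------

def _axial_angular_coordinates(points: np.ndarray, polyline: np.ndarray):
    """Arc-length and angle of each point relative to a polyline axis."""
    a = polyline[:-1]
    ab = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(ab, axis=1)
    denom = np.maximum((ab * ab).sum(axis=1), 1e-300)
    ap = points[:, None, :] - a[None]
    t = np.clip((ap * ab[None]).sum(axis=2) / denom, 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    j = np.argmin(d, axis=1)
    rows = np.arange(len(points))
    arc0 = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = arc0[j] + t[rows, j] * seg_len[j]
    tangent = ab[j] / seg_len[j][:, None]
    radial = points - closest[rows, j]
    helper = np.where(np.abs(tangent[:, [0]]) < 0.9,
                      np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
    n1 = np.cross(tangent, helper)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangent, n1)
    angle = np.degrees(np.arctan2((radial * n2).sum(axis=1),
                                  (radial * n1).sum(axis=1))) % 360.0
    return s, angle


def degrade(cloud: PointCloud, truth: GroundTruth, gaps: Sequence[Gap] = (),
            extra_noise_points: int = 0, seed: int = 0,
            ) -> Tuple[PointCloud, GroundTruth]:
    """Remove points inside the given gaps; optionally add stray outliers.

    Surviving points keep their labels; added outliers get label -1.
    """
    keep = np.ones(cloud.n, dtype=bool)
    for gap in gaps:
        polyline = (truth.trunk_polyline if gap.target == 0
                    else truth.branch_polylines[gap.target])
        on_target = truth.labels == gap.target
        if not np.any(on_target):
            continue
        s, angle = _axial_angular_coordinates(cloud.coords[on_target], polyline)
        inside = np.ones(int(on_target.sum()), dtype=bool)
        if gap.axial_range is not None:
            lo, hi = gap.axial_range
            inside &= (s >= lo) & (s <= hi)
        if gap.angular_range is not None:
            start, extent = gap.angular_range
            inside &= ((angle - start) % 360.0) <= extent
        mask = np.zeros(cloud.n, dtype=bool)
        mask[np.flatnonzero(on_target)[inside]] = True
        keep &= ~mask
    coords = cloud.coords[keep]
    labels = truth.labels[keep]
    if extra_noise_points > 0:
        rng = np.random.default_rng(seed)
        lo = cloud.coords.min(axis=0) - 0.1
        hi = cloud.coords.max(axis=0) + 0.1
        stray = rng.uniform(lo, hi, size=(extra_noise_points, 3))
        coords = np.vstack([coords, stray])
        labels = np.concatenate([labels, np.full(extra_noise_points, -1, dtype=np.int64)])
    new_truth = GroundTruth(labels=labels, traits=truth.traits,
                            trunk_polyline=truth.trunk_polyline,
                            branch_polylines=truth.branch_polylines,
                            branch_origins=truth.branch_origins, spec=truth.spec)
    return PointCloud(coords), new_truth


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _robust_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R^2 of a bisquare IRLS regression of predictions on reference values."""
    import statsmodels.api as sm

    if len(y_true) < 3 or np.std(y_true) == 0:
        return np.nan
    exog = sm.add_constant(y_true)
    fit = sm.RLM(y_pred, exog, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
    resid = y_pred - fit.fittedvalues
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y_pred - y_pred.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan


def _metric_block(y_true: np.ndarray, y_pred: np.ndarray) -> Dict[str, float]:
    err = y_pred - y_true
    with np.errstate(divide="ignore", invalid="ignore"):
        mape = float(np.mean(np.abs(err) / np.abs(y_true)) * 100.0)
    return {
        "mae": float(np.mean(np.abs(err))),
        "mape": mape,
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "r2": _robust_r2(y_true, y_pred),
        "n": int(len(y_true)),
    }


def match_branches(predicted_origins: Dict[int, np.ndarray],
                   true_origins: Dict[int, np.ndarray],
                   tolerance: float = 0.05) -> Dict[int, int]:
    """Greedy one-to-one origin matching by distance; {pred id: true id}."""
    pairs = []
    for pid, p in predicted_origins.items():
        for tid, t in true_origins.items():
            d = float(np.linalg.norm(np.asarray(p) - np.asarray(t)))
            if d <= tolerance:
                pairs.append((d, pid, tid))
    pairs.sort()
    matched: Dict[int, int] = {}
    used_true = set()
    for _, pid, tid in pairs:
        if pid in matched or tid in used_true:
            continue
        matched[pid] = tid
        used_true.add(tid)
    return matched


def evaluate(predicted: Sequence[TraitRecord], truth: Sequence[TraitRecord],
             branch_matches: Optional[Sequence[Dict[int, int]]] = None,
             ) -> EvalReport:
    """Score predicted trait records against ground truth.

    ``branch_matches`` gives, per tree, the {predicted branch id: true branch
    id} correspondence from :func:`match_branches`; without it, branch-level
    metrics pair branches by id.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must pair one record per tree")
    report = EvalReport()
    if not predicted:
        report.flags.append("empty pairing: metrics undefined")
        return report
    pairs = {"tree_height_cm": ([], []), "trunk_diameter_mm": ([], []),
             "branch_count": ([], []), "branch_diameter_mm": ([], []),
             "branch_angle_deg": ([], [])}
    for ti, (pred, ref) in enumerate(zip(predicted, truth)):
        for key, attr in (("tree_height_cm", "tree_height_cm"),
                          ("trunk_diameter_mm", "trunk_diameter_mm"),
                          ("branch_count", "branch_count")):
            p, r = getattr(pred, attr), getattr(ref, attr)
            if np.isfinite(p) and np.isfinite(r):
                pairs[key][0].append(r)
                pairs[key][1].append(p)
        match = (branch_matches[ti] if branch_matches is not None
                 else {b.branch_id: b.branch_id for b in pred.branches})
        ref_by_id = {b.branch_id: b for b in ref.branches}
        for b in pred.branches:
            tid = match.get(b.branch_id)
            if tid is None or tid not in ref_by_id:
                continue
            rb = ref_by_id[tid]
            pairs["branch_diameter_mm"][0].append(rb.diameter_mm)
            pairs["branch_diameter_mm"][1].append(b.diameter_mm)
            pairs["branch_angle_deg"][0].append(rb.inclination_deg)
            pairs["branch_angle_deg"][1].append(b.inclination_deg)
        report.branch_tp += len(match)
        report.branch_fp += len(pred.branches) - len(match)
        report.n_true_branches += len(ref.branches)
    for key, (y_true, y_pred) in pairs.items():
        if y_true:
            report.traits[key] = _metric_block(np.asarray(y_true, dtype=np.float64),
                                               np.asarray(y_pred, dtype=np.float64))
        else:
            report.flags.append(f"no pairs for {key}")
    return report


# ---------------------------------------------------------------------------
# fixture specs
# ---------------------------------------------------------------------------

def random_tree_spec(seed: int, n_branches: Optional[int] = None,
                     surface_density: float = 5e4,
                     noise_sigma: float = 2.0) -> SyntheticTreeSpec:
    """A random tree inside the trellised-orchard envelope, reproducible per seed."""
    rng = np.random.default_rng(seed)
    height = rng.uniform(2.4, 3.9)
    n = int(n_branches if n_branches is not None else rng.integers(6, 16))
    lo, hi = 0.6, height - 0.4
    # stratified placement with jitter guarantees origin separation
    slots = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    spacing = (hi - lo) / max(n - 1, 1)
    heights = slots + rng.uniform(-0.3, 0.3, n) * spacing
    azimuths = (np.arange(n) * 137.5 + rng.uniform(0, 360)) % 360.0
    branches = []
    for h, az in zip(heights, azimuths):
        incl = float(rng.uniform(30.0, 80.0))
        # tall-spindle allometry: upper branches are younger, shorter, thinner,
        # and the central leader stays the tallest and the longest axis
        age_factor = 1.0 - 0.45 * (h - lo) / max(hi - lo, 1e-9)
        length = float(rng.uniform(0.5, 1.1) * age_factor)
        headroom = max(height - h - 0.15, 0.2)
        if length * np.cos(np.radians(incl)) > headroom:
            # keep the length, open the crotch angle instead
            incl = float(np.degrees(np.arccos(headroom / length)))
        branches.append(BranchSpec(
            insertion_height=float(h),
            azimuth=float(az),
            inclination=incl,
            diameter=float(np.clip(rng.uniform(14.0, 22.0) * length / 0.8, 9.0, 26.0)),
            length=length,
            curvature=float(rng.uniform(0.0, 0.15)),
        ))
    return SyntheticTreeSpec(
        height=float(height),
        trunk_diameter_base=float(rng.uniform(42.0, 68.0)),
        trunk_taper=float(rng.uniform(4.0, 10.0)),
        trunk_lean=float(rng.uniform(0.0, 5.0)),
        branches=branches,
        surface_density=surface_density,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def suite_specs(n_trees: int = 20, base_seed: int = 0,
                surface_density: float = 5e4) -> List[SyntheticTreeSpec]:
    """The fixture suite: n random trees + a branchless pole."""
    specs = [random_tree_spec(base_seed + i, surface_density=surface_density)
             for i in range(n_trees)]
    pole = SyntheticTreeSpec(height=3.0, trunk_diameter_base=50.0, trunk_taper=6.0,
                             trunk_lean=1.0, branches=[],
                             surface_density=surface_density, noise_sigma=2.0,
                             seed=base_seed + n_trees)
    specs.append(pole)
    return specs
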
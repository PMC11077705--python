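"""Point-cloud container, file I/O, denoising and cropping.

Coordinates are metric (meters), z-up, matching terrestrial-laser-scanner
conventions.  Supported on-disk formats are ASCII/binary-little-endian PLY,
ASCII PCD and whitespace-delimited XYZ[RGB]; LAS is exposed as an optional
capability that this build reports as unavailable.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "AxisAlignedBox",
    "AffineRecord",
    "read_point_cloud",
    "write_point_cloud",
    "sor_filter",
    "crop_roi",
    "normalize_to_unit_cube",
    "LAS_AVAILABLE",
]

#: LAS/LAZ reading requires an external LAS library; this build ships without one.
LAS_AVAILABLE = False


class FormatError(ValueError):
    """Raised when a file does not parse under the named standard."""


@dataclass
class PointCloud:
    """3D points of one tree, optionally colorized.

    Attributes
    ----------
    coords : (n, 3) float64 array
        Positions in meters, z-up.
    color : (n, 3) uint8 array or None
        Per-point RGB.
    """

    coords: np.ndarray
    color: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("point coordinates must be finite")
        if self.color is not None:
            self.color = np.asarray(self.color).reshape(-1, 3)
            if len(self.color) != len(self.coords):
                raise ValueError("color must have exactly n entries")

    @property
    def n(self) -> int:
        return len(self.coords)

    def select(self, index) -> "PointCloud":
        """Subset preserving order of ``index``."""
        color = self.color[index] if self.color is not None else None
        return PointCloud(self.coords[index], color)


@dataclass
class AxisAlignedBox:
    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        self.min_corner = np.asarray(self.min_corner, dtype=np.float64).reshape(3)
        self.max_corner = np.asarray(self.max_corner, dtype=np.float64).reshape(3)
        if np.any(self.min_corner > self.max_corner):
            raise ValueError("min_corner must be <= max_corner componentwise")


@dataclass
class AffineRecord:
    """Uniform scale + translation ``y = scale * (x - offset)`` and its inverse."""

    scale: float
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.offset) * self.scale

    def invert(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) / self.scale + self.offset


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"ply", "pcd", "xyz", "las", "laz", "txt"}:
        return "xyz" if suffix == "txt" else suffix
    raise FormatError(f"cannot infer point-cloud format from {path.name!r}")


def read_point_cloud(path, format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from disk.

    Parameters
    ----------
    path : path-like
    format : {"ply", "pcd", "xyz", "las"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = (format or _sniff_format(path)).lower()
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt in {"las", "laz"}:
        raise FormatError("LAS support is not available in this build (LAS_AVAILABLE=False)")
    raise FormatError(f"unknown point-cloud format {fmt!r}")


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise FormatError(f"{path} is not a PLY file")
        fmt = None
        elements = []  # (name, count, [(prop, dtype)])
        while True:
            line = fh.readline()
            if not line:
                raise FormatError("PLY header truncated")
            tokens = line.split()
            if not tokens or tokens[0] == b"comment":
                continue
            if tokens[0] == b"format":
                fmt = tokens[1].decode()
            elif tokens[0] == b"element":
                elements.append([tokens[1].decode(), int(tokens[2]), []])
            elif tokens[0] == b"property":
                if tokens[1] == b"list":
                    elements[-1][2].append((tokens[4].decode(), "list", tokens[2].decode(), tokens[3].decode()))
                else:
                    elements[-1][2].append((tokens[2].decode(), tokens[1].decode()))
            elif tokens[0] == b"end_header":
                break
        if fmt is None:
            raise FormatError("PLY header lacks a format line")
        data = {}
        if fmt == "ascii":
            for name, count, props in elements:
                rows = []
                for _ in range(count):
                    rows.append(fh.readline().split())
                if any(len(p) > 2 for p in props):
                    # list properties (e.g. face indices) are skipped
                    continue
                arr = np.array(rows, dtype=np.float64) if rows else np.empty((0, len(props)))
                data[name] = {p[0]: arr[:, i] for i, p in enumerate(props)}
        elif fmt == "binary_little_endian":
            for name, count, props in elements:
                if any(len(p) > 2 for p in props):
                    raise FormatError("binary PLY list properties are not supported")
                dtype = np.dtype([(p[0], "<" + _PLY_DTYPES[p[1]]) for p in props])
                raw = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype, count=count)
                data[name] = {p[0]: raw[p[0]].astype(np.float64) for p in props}
        else:
            raise FormatError(f"unsupported PLY format {fmt!r}")
    if "vertex" not in data:
        raise FormatError("PLY file has no vertex element")
    vert = data["vertex"]
    try:
        coords = np.column_stack([vert["x"], vert["y"], vert["z"]])
    except KeyError as exc:
        raise FormatError("PLY vertex element lacks x/y/z") from exc
    color = None
    if all(c in vert for c in ("red", "green", "blue")):
        color = np.column_stack([vert["red"], vert["green"], vert["blue"]]).astype(np.uint8)
    cloud = PointCloud(coords, color)
    if "label" in vert:
        cloud.labels = vert["label"].astype(np.int64)  # type: ignore[attr-defined]
    return cloud


def _read_pcd(path: Path) -> PointCloud:
    fields, count, data_mode = [], None, None
    with open(path, "rb") as fh:
        while True:
            line = fh.readline().decode("ascii", "replace").strip()
            if line.startswith("#") or not line:
                continue
            key, *vals = line.split()
            if key == "FIELDS":
                fields = vals
            elif key == "POINTS":
                count = int(vals[0])
            elif key == "DATA":
                data_mode = vals[0]
                break
        if data_mode != "ascii":
            raise FormatError("only ASCII PCD files are supported")
        rows = [fh.readline().split() for _ in range(count or 0)]
    arr = np.array(rows, dtype=np.float64) if rows else np.empty((0, len(fields)))
    idx = {f: i for i, f in enumerate(fields)}
    try:
        coords = arr[:, [idx["x"], idx["y"], idx["z"]]]
    except KeyError as exc:
        raise FormatError("PCD file lacks x/y/z fields") from exc
    return PointCloud(coords)


def _read_xyz(path: Path) -> PointCloud:
    try:
        arr = np.loadtxt(path, ndmin=2, dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as whitespace XYZ") from exc
    if arr.size == 0:
        return PointCloud(np.empty((0, 3)))
    if arr.shape[1] < 3:
        raise FormatError("XYZ file needs at least 3 columns")
    color = arr[:, 3:6].astype(np.uint8) if arr.shape[1] >= 6 else None
    return PointCloud(arr[:, :3], color)


def write_point_cloud(path, cloud: PointCloud, format: Optional[str] = None,
                      labels: Optional[np.ndarray] = None) -> None:
    """Write a point cloud as ASCII PLY, PCD or XYZ.

    ``labels`` adds an integer per-point ``label`` property (PLY only), used by
    the synthetic generator to carry ground-truth structure labels.
    """
    path = Path(path)
    fmt = (format or _sniff_format(path)).lower()
    if fmt == "ply":
        _write_ply(path, cloud, labels)
    elif fmt == "pcd":
        _write_pcd(path, cloud)
    elif fmt == "xyz":
        cols = [cloud.coords]
        if cloud.color is not None:
            cols.append(cloud.color.astype(np.float64))
        np.savetxt(path, np.column_stack(cols), fmt="%.8f")
    else:
        raise FormatError(f"cannot write format {fmt!r}")


def _write_ply(path: Path, cloud: PointCloud, labels=None) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {cloud.n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        if cloud.color is not None:
            fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        if labels is not None:
            fh.write("property int label\n")
        fh.write("end_header\n")
        for i in range(cloud.n):
            parts = [f"{v:.8f}" for v in cloud.coords[i]]
            if cloud.color is not None:
                parts += [str(int(v)) for v in cloud.color[i]]
            if labels is not None:
                parts.append(str(int(labels[i])))
            fh.write(" ".join(parts) + "\n")


def _write_pcd(path: Path, cloud: PointCloud) -> None:
    with open(path, "w") as fh:
        fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
        fh.write("VERSION 0.7\nFIELDS x y z\nSIZE 8 8 8\nTYPE F F F\nCOUNT 1 1 1\n")
        fh.write(f"WIDTH {cloud.n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n")
        fh.write(f"POINTS {cloud.n}\nDATA ascii\n")
        for p in cloud.coords:
            fh.write(f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def sor_filter(cloud: PointCloud, k_neighbors: int = 6, sigma_mult: float = 1.0) -> PointCloud:
    """Statistical outlier removal.

    For each point, the mean distance to its ``k_neighbors`` nearest neighbors
    is computed; points whose mean distance exceeds
    ``global mean + sigma_mult * global std`` of those per-point means are
    dropped.  Defaults mirror the CloudCompare SOR defaults (k=6, 1 sigma).
    """
    if cloud.n <= k_neighbors:
        raise ValueError(f"sor_filter needs n > k_neighbors ({cloud.n} <= {k_neighbors})")
    tree = cKDTree(cloud.coords)
    dists, _ = tree.query(cloud.coords, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    threshold = mean_d.mean() + sigma_mult * mean_d.std()
    keep = np.flatnonzero(mean_d <= threshold)
    return cloud.select(keep)


def crop_roi(cloud: PointCloud, box: AxisAlignedBox) -> PointCloud:
    """Retain exactly the points inside the axis-aligned box (inclusive)."""
    inside = np.all((cloud.coords >= box.min_corner) & (cloud.coords <= box.max_corner), axis=1)
    return cloud.select(np.flatnonzero(inside))


def normalize_to_unit_cube(cloud: PointCloud) -> tuple[PointCloud, AffineRecord]:
    """Uniformly scale + translate the bounding box into [0, 1]^3.

    Aspect ratio is preserved: the longest bounding-box extent maps onto
    [0, 1].  Returns the transform record so downstream traits can be reported
    back in meters.
    """
    if cloud.n < 2:
        raise ValueError("normalize_to_unit_cube needs at least 2 points")
    lo = cloud.coords.min(axis=0)
    extent = cloud.coords.max(axis=0) - lo
    longest = float(extent.max())
    if longest <= 0.0:
        raise ValueError("degenerate input: zero extent")
    record = AffineRecord(scale=1.0 / longest, offset=lo)
    return PointCloud(record.apply(cloud.coords), cloud.color), record
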
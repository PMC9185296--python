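"""Benchmark statistics: error maps, ECDF, signed depth bias, missing area, cross-sections.

The primary error metric is the unsigned nearest-point distance from each
scan point to the reference cloud.  Because "distance bias" has a sign (a
biased scan sits *behind* the reference), a separate signed along-ray
statistic is provided: for each scan point the difference between its range
from the camera and the range of the reference point nearest in viewing
direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing
from scipy.spatial import cKDTree

from berrycloud.pointcloud import PointCloud
from berrycloud.synthetic import CameraPose

__all__ = [
    "ErrorMap",
    "ECDFCurve",
    "nearest_point_errors",
    "mean_error",
    "ecdf",
    "quantile",
    "signed_depth_errors",
    "missing_area_fraction",
    "cross_section",
]


@dataclass
class ErrorMap:
    """Per-source-point nearest-reference distances (mm, non-negative)."""

    distances: np.ndarray
    source_tag: str = ""
    reference_tag: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)
        if self.distances.size and (np.any(self.distances < 0) or not np.all(np.isfinite(self.distances))):
            raise ValueError("error distances must be finite and non-negative")

    def __len__(self) -> int:
        return self.distances.size


@dataclass
class ECDFCurve:
    """Right-continuous empirical CDF: sorted values and cumulative fractions."""

    sorted_values: np.ndarray
    cumulative_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.sorted_values = np.asarray(self.sorted_values, dtype=float).reshape(-1)
        self.cumulative_fraction = np.asarray(self.cumulative_fraction, dtype=float).reshape(-1)
        if np.any(np.diff(self.sorted_values) < 0) or np.any(np.diff(self.cumulative_fraction) < 0):
            raise ValueError("ECDF must be monotone non-decreasing")
        if self.cumulative_fraction.size and abs(self.cumulative_fraction[-1] - 1.0) > 1e-12:
            raise ValueError("last cumulative fraction must be 1")


def nearest_point_errors(source: PointCloud, reference: PointCloud) -> ErrorMap:
    """Exact minimum Euclidean distance from each source point to the reference."""
    if len(reference) == 0:
        raise ValueError("reference cloud must be non-empty")
    tree = cKDTree(reference.points)
    d, _ = tree.query(source.points) if len(source) else (np.empty(0), None)
    return ErrorMap(distances=np.atleast_1d(d), source_tag=source.source_tag,
                    reference_tag=reference.source_tag)


def mean_error(map: ErrorMap) -> float:
    """Arithmetic mean of the error map (mm)."""
    if len(map) == 0:
        raise ValueError("empty error map")
    return float(np.mean(map.distances))


def ecdf(map: ErrorMap) -> ECDFCurve:
    if len(map) == 0:
        raise ValueError("empty error map")
    v = np.sort(map.distances)
    f = np.arange(1, v.size + 1) / v.size
    return ECDFCurve(v, f)


def quantile(curve: ECDFCurve, q: float) -> float:
    """Smallest value whose cumulative fraction is >= q."""
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    i = int(np.searchsorted(curve.cumulative_fraction, q - 1e-12))
    i = min(i, curve.sorted_values.size - 1)
    return float(curve.sorted_values[i])


def signed_depth_errors(source: PointCloud, reference: PointCloud,
                        camera_origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Signed along-ray depth error per source point (mm; positive = behind).

    For each source point, the reference point nearest in viewing *direction*
    (unit ray from the camera origin) is found, and the difference of ranges
    from the camera is returned.  With a dense reference this recovers the
    along-ray displacement directly, which the unsigned nearest-point metric
    underestimates at oblique incidence.
    """
    if len(reference) == 0:
        raise ValueError("reference cloud must be non-empty")
    o = np.asarray(camera_origin, dtype=float).reshape(3)
    rs = source.points - o
    rr = reference.points - o
    ds = np.linalg.norm(rs, axis=1)
    dr = np.linalg.norm(rr, axis=1)
    if np.any(ds == 0) or np.any(dr == 0):
        raise ValueError("points coincide with the camera origin")
    tree = cKDTree(rr / dr[:, None])
    # the reference cloud contains back surfaces too: among the nearest
    # directions, the *front* surface (minimum range) is the one the camera saw
    k = min(12, len(reference))
    _, j = tree.query(rs / ds[:, None], k=k)
    j = np.atleast_2d(j.reshape(len(source), k))
    return ds - dr[j].min(axis=1)


def _project(points: np.ndarray, pose: CameraPose) -> np.ndarray:
    u, v, w = pose.basis()
    rel = points - pose.origin
    depth = rel @ w
    if np.any(depth <= 0):
        raise ValueError("all points must lie in front of the camera")
    return np.column_stack([(rel @ u) / depth, (rel @ v) / depth])


def _coverage(points2d: np.ndarray, lo: np.ndarray, hi: np.ndarray, image_size: int) -> np.ndarray:
    ij = np.floor((points2d - lo) / (hi - lo) * image_size).astype(int)
    ij = np.clip(ij, 0, image_size - 1)
    img = np.zeros((image_size, image_size), dtype=bool)
    img[ij[:, 1], ij[:, 0]] = True
    # 1-pixel morphological closing bridges point-sampling pinholes
    return binary_closing(img, structure=np.ones((3, 3)))


def missing_area_fraction(scan: PointCloud, reference: PointCloud,
                          pose: CameraPose, image_size: int = 96) -> float:
    """Percentage of projected scan area missing relative to the reference.

    Both clouds are rasterised by perspective projection onto the same
    ``image_size`` x ``image_size`` grid (framed on the reference silhouette
    with a 5% margin); a pixel is covered if at least one point projects into
    it, after a 1-pixel morphological closing.  Returns
    ``covered%(reference) - covered%(scan)``, clamped at 0, in percent of the
    image.
    """
    if len(reference) == 0:
        raise ValueError("reference cloud must be non-empty")
    ref2d = _project(reference.points, pose)
    lo, hi = ref2d.min(axis=0), ref2d.max(axis=0)
    margin = 0.05 * (hi - lo)
    lo, hi = lo - margin, hi + margin
    if np.any(hi <= lo):
        raise ValueError("degenerate view: reference projects to a point or line")
    ref_cov = _coverage(ref2d, lo, hi, image_size).mean() * 100.0
    if len(scan) == 0:
        scan_cov = 0.0
    else:
        scan_cov = _coverage(_project(scan.points, pose), lo, hi, image_size).mean() * 100.0
    return max(float(ref_cov - scan_cov), 0.0)


def cross_section(cloud: PointCloud, axis_value: float, thickness: float,
                  plane: str = "XZ") -> np.ndarray:
    """2D polyline of points within a thin slab, for berry-profile plots.

    ``plane="XZ"`` slices at ``y = axis_value`` and returns (x, z) pairs
    sorted by x; ``plane="YZ"`` slices at ``x = axis_value`` and returns
    (y, z) pairs sorted by y.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if plane not in ("XZ", "YZ"):
        raise ValueError("plane must be 'XZ' or 'YZ'")
    slab_axis = 1 if plane == "XZ" else 0
    lateral_axis = 0 if plane == "XZ" else 1
    m = np.abs(cloud.points[:, slab_axis] - axis_value) <= thickness / 2.0
    pts = cloud.points[m][:, [lateral_axis, 2]]
    return pts[np.argsort(pts[:, 0], kind="stable")]
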
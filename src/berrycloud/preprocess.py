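"""Scan cleaning: flying-pixel rejection by normal angle, statistical outlier removal.

Raw time-of-flight and LiDAR scans carry spurious "flying pixels" at object
silhouettes where a sensor pixel mixes foreground and background returns.
They are removed in two passes: first by rejecting points whose surface
normal is nearly perpendicular to the viewing direction (threshold 85
degrees, the empirical value that separates silhouette points from real
surface), then by statistical outlier removal over mean k-nearest-neighbour
distances (k = 6, one standard deviation of the cloud-wide distribution).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from berrycloud.pointcloud import PointCloud

__all__ = ["normal_angle_filter", "statistical_outlier_removal"]


def normal_angle_filter(cloud: PointCloud, view_origin=(0.0, 0.0, 0.0),
                        max_angle_deg: float = 85.0) -> PointCloud:
    """Keep points whose normal is within ``max_angle_deg`` of the viewing direction.

    The angle is measured between the point's normal and the direction from
    the point toward ``view_origin`` (viewpoint-relative, since flying-pixel
    geometry is): silhouette points at grazing incidence exceed the threshold
    and are removed.  Order is preserved.
    """
    if cloud.normals is None:
        raise ValueError("normal_angle_filter requires normals; run estimate_normals first")
    if not 0.0 < max_angle_deg < 180.0:
        raise ValueError("max_angle_deg must be in (0, 180)")
    view_origin = np.asarray(view_origin, dtype=float).reshape(3)
    to_view = view_origin[None, :] - cloud.points
    lens = np.linalg.norm(to_view, axis=1)
    lens[lens == 0] = 1.0
    cosang = np.einsum("ni,ni->n", cloud.normals, to_view / lens[:, None])
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return cloud.select(angle <= max_angle_deg)


def statistical_outlier_removal(cloud: PointCloud, k: int = 6, nsigma: float = 1.0) -> PointCloud:
    """Remove isolated points by the mean-kNN-distance criterion.

    For each point, ``d_i`` is the mean distance to its ``k`` exact nearest
    neighbours (self excluded).  Points with
    ``d_i > mean(d) + nsigma * sd(d)``, with the statistics taken over the
    whole cloud, are removed.  Order is preserved.
    """
    n = len(cloud)
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=k + 1)   # column 0 is the point itself
    d = dist[:, 1:].mean(axis=1)
    thresh = d.mean() + nsigma * d.std()
    return cloud.select(d <= thresh)
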
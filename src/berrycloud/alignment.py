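"""Rigid registration of a camera scan to the reference scan.

Closed-form landmark alignment (Kabsch / orthogonal Procrustes on paired
points), point-to-point ICP refinement, a projective scale correction for
depth-biased scans, and transform application.

The rigid model is ``x -> s * R @ x + T`` with R a proper rotation
(det +1, never a reflection), T in millimetres and s a uniform scale
(default 1).  Scale is estimated separately by :func:`projective_scale` and
composed — it is never optimised jointly inside ICP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from berrycloud.pointcloud import PointCloud

__all__ = [
    "RigidTransform",
    "ICPResult",
    "DegenerateConfigurationError",
    "landmark_align",
    "apply_transform",
    "icp_align",
    "projective_scale",
]


class DegenerateConfigurationError(ValueError):
    """Landmark configuration too degenerate to define a rigid transform."""


@dataclass
class RigidTransform:
    """Similarity transform ``x -> s * R @ x + T`` (s defaults to 1)."""

    R: np.ndarray
    T: np.ndarray
    s: float = 1.0

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.T = np.asarray(self.T, dtype=float).reshape(3)
        if np.linalg.norm(self.R.T @ self.R - np.eye(3)) > 1e-8:
            raise ValueError("R must be orthonormal")
        if np.linalg.det(self.R) <= 0:
            raise ValueError("R must be a proper rotation (det +1)")
        if self.s <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.s * points @ self.R.T + self.T

    def inverse(self) -> "RigidTransform":
        Rinv = self.R.T
        return RigidTransform(Rinv, -(Rinv @ self.T) / self.s, 1.0 / self.s)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(self.R @ other.R,
                              self.s * self.R @ other.T + self.T,
                              self.s * other.s)

    def to_dict(self) -> dict:
        """Serialise as 12 numbers (row-major R, then T) plus s."""
        return {"R": self.R.reshape(-1).tolist(), "T": self.T.tolist(), "s": self.s}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["R"]).reshape(3, 3), np.asarray(d["T"]), float(d.get("s", 1.0)))


@dataclass
class ICPResult:
    transform: RigidTransform
    iterations: int
    final_rms_mm: float
    converged: bool
    rms_history: list = field(default_factory=list)


def _as_points(x) -> np.ndarray:
    if isinstance(x, PointCloud):
        return x.points
    return np.asarray(x, dtype=float).reshape(-1, 3)


def landmark_align(X, Y) -> RigidTransform:
    """Closed-form least-squares rigid alignment of paired landmarks.

    Returns the global minimiser of ``sum_i || Y_i - R @ X_i - T ||^2`` over
    proper rotations R and translations T, via SVD of the centred
    cross-covariance (Kabsch).  X and Y must be in correspondence by index.
    """
    Xp, Yp = _as_points(X), _as_points(Y)
    if Xp.shape != Yp.shape:
        raise ValueError("X and Y must have the same point count")
    n = Xp.shape[0]
    if n < 3:
        raise DegenerateConfigurationError(f"need at least 3 landmarks, got {n}")
    xc, yc = Xp.mean(axis=0), Yp.mean(axis=0)
    H = (Xp - xc).T @ (Yp - yc)
    U, S, Vt = np.linalg.svd(H)
    # collinear configurations leave the rotation about the line unconstrained
    if S[1] <= 1e-9 * max(S[0], 1e-300):
        raise DegenerateConfigurationError("landmarks are collinear (or coincident)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    T = yc - R @ xc
    return RigidTransform(R, T)


def alignment_rms(X, Y, t: RigidTransform) -> float:
    """RMS residual of paired landmarks under transform ``t``."""
    Xp, Yp = _as_points(X), _as_points(Y)
    return float(np.sqrt(np.mean(np.sum((Yp - t.apply(Xp)) ** 2, axis=1))))


def apply_transform(cloud: PointCloud, t: RigidTransform) -> PointCloud:
    """Map each point to ``s * R @ x + T``; normals are rotated by R only."""
    return PointCloud(
        points=t.apply(cloud.points),
        normals=None if cloud.normals is None else cloud.normals @ t.R.T,
        labels=None if cloud.labels is None else cloud.labels.copy(),
        source_tag=cloud.source_tag,
    )


def icp_align(
    source: PointCloud,
    target: PointCloud,
    max_iterations: int = 50,
    rms_tolerance_mm: float = 1e-3,
    init: Optional[RigidTransform] = None,
    max_correspondence_mm: Optional[float] = None,
) -> ICPResult:
    """Point-to-point ICP of ``source`` onto ``target``.

    Alternates exact nearest-neighbour correspondence with the closed-form
    landmark solve until the matched RMS changes by less than
    ``rms_tolerance_mm`` or the iteration cap is reached.  The matched RMS is
    non-increasing across iterations.  Correspondences beyond
    ``max_correspondence_mm`` are discarded when set (default: unlimited).
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("ICP requires non-empty source and target clouds")
    init = RigidTransform.identity() if init is None else init
    # ICP never optimises scale: fold the (fixed) incoming scale into the
    # source coordinates and solve for the rigid part only.
    s0 = init.s
    Xs = s0 * source.points
    t = RigidTransform(init.R, init.T, 1.0)
    tree = cKDTree(target.points)

    def rms_of(tr: RigidTransform) -> float:
        d, _ = tree.query(tr.apply(Xs))
        return float(np.sqrt(np.mean(d**2)))

    if max_iterations == 0:
        return ICPResult(RigidTransform(init.R, init.T, s0), 0, rms_of(t), False, [])
    history: list[float] = []
    prev_rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        d, j = tree.query(t.apply(Xs))
        if max_correspondence_mm is not None:
            keep = d <= max_correspondence_mm
            if int(keep.sum()) < 3:
                break
            t_new = landmark_align(Xs[keep], target.points[j[keep]])
        else:
            t_new = landmark_align(Xs, target.points[j])
        rms = rms_of(t_new)
        t = t_new
        history.append(rms)
        if abs(prev_rms - rms) < rms_tolerance_mm:
            converged = True
            break
        prev_rms = rms
    final = history[-1] if history else rms_of(t)
    return ICPResult(RigidTransform(t.R, t.T, s0), it, final, converged, history)


def projective_scale(source: PointCloud, reference: PointCloud, camera_origin=(0.0, 0.0, 0.0)) -> float:
    """Scale factor correcting a depth-biased scan sitting behind the reference.

    For each source point the reference point nearest in viewing *direction*
    (unit ray from the camera origin) is matched — taking the closest-range
    candidate among the nearest directions, i.e. the camera-facing surface —
    and the median ratio of reference to source range is returned.  Applying
    ``s`` as a uniform scale about the camera origin maps the biased scan
    onto the reference depth shell (a projective correction: points
    displaced along their viewing rays scale radially about the optical
    centre).  Matching along rays keeps the estimate exact for along-ray
    displacement and valid when the reference is a full-surround model.
    """
    if len(source) == 0 or len(reference) == 0:
        raise ValueError("projective_scale requires non-empty clouds")
    o = np.asarray(camera_origin, dtype=float).reshape(3)
    rs = source.points - o
    rr = reference.points - o
    d_src = np.linalg.norm(rs, axis=1)
    d_ref = np.linalg.norm(rr, axis=1)
    if np.any(d_src <= 0) or np.any(d_ref <= 0):
        raise ValueError("points must not coincide with the camera origin")
    us = rs / d_src[:, None]
    ur = rr / d_ref[:, None]
    k_ref = min(12, len(reference))
    _, j = cKDTree(ur).query(us, k=k_ref)
    j = np.atleast_2d(j.reshape(len(source), k_ref))
    d_ref_front = d_ref[j].min(axis=1)
    # symmetric front-depth for the source itself, so a full-surround source
    # compared against itself yields exactly 1
    k_src = min(12, len(source))
    _, jj = cKDTree(us).query(us, k=k_src)
    jj = np.atleast_2d(jj.reshape(len(source), k_src))
    d_src_front = d_src[jj].min(axis=1)
    s = float(np.median(d_ref_front / d_src_front))
    if s <= 0:
        raise ValueError("non-positive scale estimate; check camera origin")
    return s


def scale_about_origin(s: float, camera_origin=(0.0, 0.0, 0.0)) -> RigidTransform:
    """RigidTransform performing a uniform scale ``s`` about ``camera_origin``."""
    o = np.asarray(camera_origin, dtype=float).reshape(3)
    return RigidTransform(np.eye(3), (1.0 - s) * o, s)
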
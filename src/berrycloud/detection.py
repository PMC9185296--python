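"""Individual-berry detection: RANSAC sphere segmentation, least-squares
refinement, matching against reference spheres, and median statistics.

Detection is greedy sequential RANSAC: hypothesise spheres from exact
4-point solves, keep the best-supported candidate, peel off its inliers and
repeat.  Each surviving segment is refined with an algebraic least-squares
sphere fit.  Detected spheres are matched to their nearest reference centre
(many-to-one allowed); the lateral (2D) position difference excludes the
depth axis so it is not dominated by any distance bias, and summary medians
exclude fitted spheres larger than 20 mm radius (implausibly large for a
berry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from berrycloud.pointcloud import PointCloud
from berrycloud.synthetic import Sphere

__all__ = [
    "SphereSegment",
    "SphereMatch",
    "MatchStats",
    "FitError",
    "fit_sphere_lsq",
    "ransac_detect_spheres",
    "match_spheres",
    "sphere_match_stats",
]


class FitError(ValueError):
    """Degenerate point configuration for sphere fitting."""


@dataclass
class SphereSegment:
    sphere: Sphere
    point_indices: np.ndarray
    inlier_rms_mm: float


@dataclass
class SphereMatch:
    detected: Sphere
    reference: Sphere
    reference_index: int
    position_diff_2d_mm: float
    radius_diff_mm: float


@dataclass
class MatchStats:
    count: int
    median_radius_diff_mm: float
    median_position_diff_2d_mm: float


def fit_sphere_lsq(points) -> Sphere:
    """Algebraic least-squares sphere (linearised ``||x||^2`` formulation).

    Solves ``2 x . c + d = ||x||^2`` for centre c and ``d = r^2 - ||c||^2``.
    Exact on noiseless spherical data, including the minimal 4-point case.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 4:
        raise FitError("sphere fit needs at least 4 points")
    # centre the data for conditioning at large camera-frame offsets
    mu = pts.mean(axis=0)
    q = pts - mu
    A = np.hstack([2.0 * q, np.ones((q.shape[0], 1))])
    b = np.einsum("ni,ni->n", q, q)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-8 * max(sv[0], 1e-300):
        raise FitError("points are coplanar or otherwise degenerate")
    c = sol[:3]
    r2 = sol[3] + float(c @ c)
    if r2 <= 0:
        raise FitError("degenerate fit: non-positive squared radius")
    return Sphere(center=c + mu, radius=float(np.sqrt(r2)))


def _solve_4pt(quad: np.ndarray) -> Optional[tuple]:
    """Exact sphere through 4 points; None when near-coplanar."""
    mu = quad.mean(axis=0)
    q = quad - mu
    A = np.hstack([2.0 * q, np.ones((4, 1))])
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < 1e-8 * max(sv[0], 1e-300):
        return None
    b = np.einsum("ni,ni->n", q, q)
    sol = np.linalg.solve(A, b)
    c = sol[:3]
    r2 = sol[3] + float(c @ c)
    if r2 <= 0:
        return None
    return c + mu, float(np.sqrt(r2))


def _component_of(points: np.ndarray, member: np.ndarray, seed_idx: Optional[int],
                  link_radius_mm: float) -> np.ndarray:
    """Boolean mask of the connected component of ``member`` points containing
    ``seed_idx`` (largest component when the seed is not a member).

    Connectivity links points closer than ``link_radius_mm``.  This drops
    inlier patches grazed on *other* berries by an over-large candidate
    sphere, which would otherwise inflate the refit radius.
    """
    idx = np.flatnonzero(member)
    if idx.size == 0:
        return member
    sub = points[idx]
    tree = cKDTree(sub)
    pairs = tree.query_pairs(link_radius_mm, output_type="ndarray")
    n = idx.size
    if pairs.size:
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n)
    pos = np.searchsorted(idx, seed_idx) if seed_idx is not None else -1
    if seed_idx is not None and pos < n and idx[pos] == seed_idx:
        target = comp[pos]
    else:
        target = np.bincount(comp).argmax()
    mask = np.zeros_like(member)
    mask[idx[comp == target]] = True
    return mask


def ransac_detect_spheres(cloud: PointCloud, epsilon_mm: float = 1.5,
                          min_support: int = 30, max_radius_mm: float = 20.0,
                          max_iterations: int = 400, seed: int = 0,
                          sample_radius_mm: Optional[float] = None,
                          link_radius_mm: float = 3.0) -> list:
    """Greedy sequential RANSAC sphere detection and segmentation.

    Per round: draw a seed point uniformly and its three companions from the
    seed's ``sample_radius_mm`` neighbourhood (default ``1.5 * max_radius_mm``
    — without locality a 4-point sample almost never lands on a single berry
    in a many-berry cloud), solve the exact 4-point sphere, and count inliers
    within ``epsilon_mm`` of the surface; after ``max_iterations`` hypotheses
    the best candidate (if its support reaches ``min_support`` and radius is
    at most ``max_radius_mm``) is refined by least squares, its inliers are
    assigned and removed, and the next round starts.  Stops when no candidate
    qualifies.  Each point belongs to at most one segment; deterministic for
    a fixed seed.
    """
    if min_support < 4:
        raise ValueError("min_support must be >= 4")
    if sample_radius_mm is None:
        sample_radius_mm = 1.5 * max_radius_mm
    rng = np.random.default_rng(seed)
    n = len(cloud)
    segments: list[SphereSegment] = []
    remaining = np.arange(n)
    failed_rounds = 0
    while remaining.size >= min_support and failed_rounds < 5:
        pts = cloud.points[remaining]
        tree = cKDTree(pts)
        best_count = 0
        best: Optional[tuple] = None
        seeds = rng.integers(0, remaining.size, size=max_iterations)
        neighbourhoods = tree.query_ball_point(pts[seeds], sample_radius_mm)
        for s0, nbrs in zip(seeds, neighbourhoods):
            nbrs = [i for i in nbrs if i != s0]
            if len(nbrs) < 3:
                continue
            s = np.concatenate([[s0], rng.choice(nbrs, size=3, replace=False)])
            res = _solve_4pt(pts[s])
            if res is None:
                continue
            c, r = res
            if r > max_radius_mm:
                continue
            dev = np.abs(np.linalg.norm(pts - c, axis=1) - r)
            count = int(np.count_nonzero(dev <= epsilon_mm))
            if count > best_count:
                best_count = count
                best = (c, r, dev <= epsilon_mm, int(s0))
        if best is None or best_count < min_support:
            break
        c, r, inl, s0 = best
        # refinement: keep the connected inlier patch around the sample seed
        # (candidate spheres can graze neighbouring berries) and refit
        for _ in range(2):
            comp = _component_of(pts, inl, s0, link_radius_mm)
            if int(comp.sum()) < 4:
                break
            try:
                refined = fit_sphere_lsq(pts[comp])
            except FitError:
                break
            if refined.radius > max_radius_mm:
                break
            c, r = refined.center, float(refined.radius)
            inl = np.abs(np.linalg.norm(pts - c, axis=1) - r) <= epsilon_mm
        inl = _component_of(pts, inl, s0, link_radius_mm)
        if int(inl.sum()) < min_support:
            # the best candidate collapsed under component filtering; retry
            # the round with fresh samples before giving up entirely
            failed_rounds += 1
            continue
        failed_rounds = 0
        dev = np.abs(np.linalg.norm(pts[inl] - c, axis=1) - r)
        segments.append(SphereSegment(
            sphere=Sphere(center=c, radius=float(r)),
            point_indices=remaining[inl],
            inlier_rms_mm=float(np.sqrt(np.mean(dev**2))),
        ))
        remaining = remaining[~inl]
    return segments


def match_spheres(detected: Sequence[Sphere], reference: Sequence[Sphere]) -> list:
    """Match each detected sphere to its nearest reference centre (KNN, 3D).

    Matching uses the full 3D centre distance; the reported position
    difference is lateral only (depth axis Z excluded), and the radius
    difference is detected minus reference.  Many-to-one matches are allowed.
    """
    if len(reference) == 0:
        raise ValueError("reference sphere list must be non-empty")
    ref_centers = np.array([s.center for s in reference]).reshape(-1, 3)
    tree = cKDTree(ref_centers)
    matches: list[SphereMatch] = []
    for det in detected:
        _, j = tree.query(det.center)
        ref = reference[int(j)]
        diff2d = float(np.linalg.norm((det.center - ref.center)[:2]))
        matches.append(SphereMatch(
            detected=det, reference=ref, reference_index=int(j),
            position_diff_2d_mm=diff2d,
            radius_diff_mm=float(det.radius - ref.radius),
        ))
    return matches


def sphere_match_stats(matches: Sequence[SphereMatch], max_radius_mm: float = 20.0) -> MatchStats:
    """Median radius / 2D-position differences over plausible matches.

    Matches whose *detected* radius exceeds ``max_radius_mm`` are ignored
    (over-large fitted spheres are artefacts of under-segmentation); medians
    are robust to the remaining stragglers.  An empty summary is returned as
    count 0 with NaN medians.
    """
    kept = [m for m in matches if m.detected.radius <= max_radius_mm]
    if not kept:
        return MatchStats(0, float("nan"), float("nan"))
    return MatchStats(
        count=len(kept),
        median_radius_diff_mm=float(np.median([m.radius_diff_mm for m in kept])),
        median_position_diff_2d_mm=float(np.median([m.position_diff_2d_mm for m in kept])),
    )
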
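"""Synthetic grape-bunch geometry and depth-camera artifact simulation.

A grape bunch is modelled as a collection of near-spherical berries packed
around a vertical rachis axis.  Two kinds of scans are rendered from it:

* a dense multi-view *reference* scan — uniform surface sampling of the
  union of spheres, standing in for a photogrammetry reconstruction;
* single-viewpoint *depth-camera* scans — one ray per angular grid cell,
  corrupted by a parametric :class:`ArtifactModel` describing one camera
  technology.

Artifact classes emulated (applied in this order — physical effects before
sampling effects before sensor noise):

1. **subsurface-scattering displacement** (ToF/LiDAR, unless painted): each
   surface point is pushed along its viewing ray away from the camera by
   ``depth_bias_mm + distortion_amp_mm * (standoff_ref_mm / D) * cos(theta)**p``
   where ``theta`` is the angle at the berry centre from the berry's
   camera-facing pole.  The bias term shifts the whole berry back; the
   sharply pole-peaked distortion term produces the pointed per-berry apex
   whose amplitude grows as the camera moves closer;
2. **valley smoothing** (active stereo): Gaussian smoothing of the depth
   image, filling concavities between berries;
3. **depth quantisation** (structured light, coarse ToF depth maps);
4. **dropout** biased toward inter-berry valleys (structured light missing
   area);
5. **flying pixels**: silhouette-edge points displaced along the ray to a
   depth between the two surfaces;
6. isotropic Gaussian **noise**.

All rendering is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from berrycloud.alignment import RigidTransform
from berrycloud.pointcloud import PointCloud

__all__ = [
    "Sphere",
    "BunchModel",
    "BunchConfig",
    "ArtifactModel",
    "CameraPose",
    "GenerationError",
    "generate_bunch",
    "render_reference_scan",
    "render_depth_scan",
    "apply_scatter_distortion",
    "chequerboard_landmarks",
    "preset",
    "PRESETS",
]

TECHNOLOGIES = ("reference", "structured_light", "active_stereo", "tof", "lidar")

#: grid-neighbour depth gap (mm) beyond which a point counts as a silhouette
#: edge for the flying-pixel model — larger than any quantisation step,
#: smaller than a berry diameter.
FLYING_PIXEL_GAP_MM = 5.0


class GenerationError(RuntimeError):
    """Bunch generation could not satisfy the packing constraint."""


@dataclass
class Sphere:
    """A berry: centre (mm, camera frame) and radius (mm)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class BunchConfig:
    """Generation parameters for a synthetic grape bunch.

    The defaults emulate a table-grape bunch scanned at ~600 mm standoff:
    ~30 berries with radii around 13.7 mm (the median berry radius measured
    on dense reference scans of real bunches), attached around a vertical
    rachis axis.  ``radius_sd`` of 1.5 mm keeps sampled radii within
    10–18 mm; sampling is truncated-normal (out-of-range draws rejected).
    """

    n_berries: int = 30
    radius_mean_mm: float = 13.7
    radius_sd_mm: float = 1.5
    radius_min_mm: float = 10.0
    radius_max_mm: float = 18.0
    #: lateral distance of berry centres from the rachis axis (mm)
    cluster_radius_mm: float = 34.0
    #: vertical extent of the bunch along the rachis (mm)
    cluster_length_mm: float = 140.0
    #: bunch centre in the camera frame (mm); +Z is depth
    center: tuple = (0.0, 0.0, 600.0)
    #: two berries may interpenetrate by at most this fraction of the
    #: smaller radius (touching berries, as in a real bunch)
    max_overlap_frac: float = 0.4
    max_attempts_per_berry: int = 2000


@dataclass
class BunchModel:
    """Ground-truth berry geometry plus generation metadata."""

    berries: list
    seed: int
    config: BunchConfig

    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.berries]).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.berries])

    @property
    def centroid(self) -> np.ndarray:
        return self.centers().mean(axis=0)


@dataclass
class ArtifactModel:
    """Parametric corruption applied by one camera technology.

    ``painted=True`` models spraying the berries with opaque paint, which
    suppresses subsurface scattering: the effective depth bias and per-berry
    distortion are forced to zero while sampling artifacts (quantisation,
    dropout, flying pixels, noise) are unchanged.
    """

    technology: str = "reference"
    depth_bias_mm: float = 0.0
    distortion_amp_mm: float = 0.0
    distortion_exponent: float = 12.0
    standoff_ref_mm: float = 350.0
    quantisation_step_mm: float = 0.0
    valley_sigma_mm: float = 0.0
    dropout_fraction: float = 0.0
    flying_pixel_rate: float = 0.0
    noise_sd_mm: float = 0.0
    painted: bool = False

    def __post_init__(self) -> None:
        if self.technology not in TECHNOLOGIES:
            raise ValueError(f"unknown technology {self.technology!r}")
        for name in ("dropout_fraction", "flying_pixel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("depth_bias_mm", "distortion_amp_mm", "standoff_ref_mm",
                     "quantisation_step_mm", "valley_sigma_mm", "noise_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def effective_bias_mm(self) -> float:
        return 0.0 if self.painted else self.depth_bias_mm

    @property
    def effective_distortion_amp_mm(self) -> float:
        return 0.0 if self.painted else self.distortion_amp_mm

    @property
    def scatters(self) -> bool:
        return (self.technology in ("tof", "lidar")) and not self.painted


#: Per-technology presets.  Depth biases for the time-of-flight and LiDAR
#: presets (7 and 8.5 mm) are the peak displacements measured on single
#: painted-vs-unpainted berries; the distortion amplitude/exponent split is a
#: modelling choice documented in docs/methods.md.  The structured-light
#: dropout fraction is calibrated so the preset loses about 20% of its
#: projected scan area relative to the reference render.
PRESETS = {
    "reference": ArtifactModel(technology="reference"),
    "structured_light": ArtifactModel(
        technology="structured_light",
        quantisation_step_mm=7.0,
        dropout_fraction=0.60,
        noise_sd_mm=0.5,
    ),
    "active_stereo": ArtifactModel(
        technology="active_stereo",
        valley_sigma_mm=2.5,
        noise_sd_mm=0.3,
    ),
    "tof": ArtifactModel(
        technology="tof",
        depth_bias_mm=7.0,
        distortion_amp_mm=2.5,
        distortion_exponent=12.0,
        standoff_ref_mm=350.0,
        quantisation_step_mm=2.0,
        flying_pixel_rate=0.10,
        noise_sd_mm=1.0,
    ),
    "lidar": ArtifactModel(
        technology="lidar",
        depth_bias_mm=8.5,
        distortion_amp_mm=2.0,
        distortion_exponent=12.0,
        standoff_ref_mm=350.0,
        flying_pixel_rate=0.03,
        noise_sd_mm=1.0,
    ),
}


def preset(technology: str, painted: bool = False) -> ArtifactModel:
    """Return a copy of the named technology preset."""
    if technology not in PRESETS:
        raise ValueError(f"unknown preset {technology!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[technology], painted=painted)


@dataclass
class CameraPose:
    """Single-viewpoint camera pose: optical centre and look-at target (mm)."""

    origin: np.ndarray
    look_at: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.look_at = np.asarray(self.look_at, dtype=float).reshape(3)
        if np.allclose(self.origin, self.look_at):
            raise ValueError("camera origin must differ from look_at")

    @property
    def standoff_mm(self) -> float:
        return float(np.linalg.norm(self.look_at - self.origin))

    @property
    def view_axis(self) -> np.ndarray:
        d = self.look_at - self.origin
        return d / np.linalg.norm(d)

    def basis(self) -> tuple:
        """Right-handed (u, v, w) with w the viewing axis."""
        w = self.view_axis
        up = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(up, w)) > 0.99:
            up = np.array([1.0, 0.0, 0.0])
        u = np.cross(up, w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        return u, v, w


def _pair_overlap(a: Sphere, b: Sphere) -> float:
    """Interpenetration depth r_a + r_b - d (negative when separated)."""
    return a.radius + b.radius - float(np.linalg.norm(a.center - b.center))


def generate_bunch(config: Optional[BunchConfig] = None, seed: int = 0) -> BunchModel:
    """Place berries around a vertical rachis axis by rejection sampling.

    Deterministic for a fixed seed.  Every pair of berries interpenetrates
    by at most ``max_overlap_frac`` of the smaller radius; a single-berry
    bunch sits exactly at the cluster centre.
    """
    config = config or BunchConfig()
    if config.n_berries < 1:
        raise ValueError("berry count must be >= 1")
    if config.radius_mean_mm <= 0:
        raise ValueError("radius mean must be positive")
    rng = np.random.default_rng(seed)
    center = np.asarray(config.center, dtype=float)

    def draw_radius() -> float:
        for _ in range(1000):
            r = rng.normal(config.radius_mean_mm, config.radius_sd_mm)
            if config.radius_min_mm <= r <= config.radius_max_mm:
                return float(r)
        return config.radius_mean_mm

    berries: list[Sphere] = []
    if config.n_berries == 1:
        return BunchModel([Sphere(center.copy(), draw_radius())], seed, config)
    for i in range(config.n_berries):
        placed = False
        for _ in range(config.max_attempts_per_berry):
            r = draw_radius()
            y = rng.uniform(-config.cluster_length_mm / 2, config.cluster_length_mm / 2)
            phi = rng.uniform(0, 2 * np.pi)
            rho = config.cluster_radius_mm * np.sqrt(rng.uniform(0.05, 1.0))
            c = center + np.array([rho * np.cos(phi), y, rho * np.sin(phi)])
            cand = Sphere(c, r)
            ok = all(
                _pair_overlap(cand, b) <= config.max_overlap_frac * min(cand.radius, b.radius)
                for b in berries
            )
            if ok:
                berries.append(cand)
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place berry {i + 1}/{config.n_berries} after "
                f"{config.max_attempts_per_berry} attempts; loosen the packing config"
            )
    return BunchModel(berries, seed, config)


def render_reference_scan(bunch: BunchModel, density: float = 1.0, seed: int = 0) -> PointCloud:
    """Uniform surface sampling of the union of berries (photogrammetry-like).

    Each berry contributes ``round(density * 4 pi r^2)`` uniformly distributed
    surface points; points buried inside another berry are removed, so the
    returned count tracks ``density x exposed area``.  Labels hold the owning
    berry index.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    centers, radii = bunch.centers(), bunch.radii()
    pts, labels = [], []
    for i, (c, r) in enumerate(zip(centers, radii)):
        n = max(int(round(density * 4.0 * np.pi * r**2)), 1)
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts.append(c + r * d)
        labels.append(np.full(n, i))
    points = np.vstack(pts)
    labels = np.concatenate(labels)
    # remove points interior to any *other* berry
    keep = np.ones(len(points), dtype=bool)
    for j, (c, r) in enumerate(zip(centers, radii)):
        inside = np.linalg.norm(points - c, axis=1) < r - 1e-9
        inside &= labels != j
        keep &= ~inside
    return PointCloud(points=points[keep], labels=labels[keep], source_tag="reference")


def _scatter_displacement_mm(cos_theta: np.ndarray, standoff_mm: float,
                             artifact: ArtifactModel) -> np.ndarray:
    """Along-ray displacement bias + amp * (D_ref / D) * cos(theta)**p."""
    c = np.clip(cos_theta, 0.0, 1.0)
    amp = artifact.effective_distortion_amp_mm * (artifact.standoff_ref_mm / standoff_mm)
    return artifact.effective_bias_mm + amp * c**artifact.distortion_exponent


def apply_scatter_distortion(point, berry: Sphere, pose: CameraPose,
                             artifact: ArtifactModel):
    """Displace one on-surface point along its viewing ray (subsurface model).

    ``theta`` is the angle at the berry centre between the point and the
    berry's camera-facing pole; the displacement is maximal at the pole,
    producing the pointed apex seen in ToF/LiDAR berry scans.
    """
    if artifact.technology not in ("tof", "lidar"):
        raise ValueError("scatter distortion applies to tof/lidar technologies only")
    if artifact.painted:
        raise ValueError("painted berries do not scatter; no distortion to apply")
    p = np.asarray(point, dtype=float).reshape(3)
    w = p - berry.center
    wn = np.linalg.norm(w)
    if wn < 1e-12:
        raise ValueError("point coincides with the berry centre; theta undefined")
    pole = pose.origin - berry.center
    pole = pole / np.linalg.norm(pole)
    cos_theta = float(np.dot(w / wn, pole))
    ray = p - pose.origin
    ray = ray / np.linalg.norm(ray)
    delta = _scatter_displacement_mm(np.array([cos_theta]), pose.standoff_mm, artifact)[0]
    return p + delta * ray


def _first_hit(origins: np.ndarray, dirs: np.ndarray, centers: np.ndarray,
               radii: np.ndarray) -> tuple:
    """Smallest positive ray-sphere intersection per ray; label -1 = miss."""
    n = dirs.shape[0]
    t_best = np.full(n, np.inf)
    label = np.full(n, -1)
    for j, (c, r) in enumerate(zip(centers, radii)):
        oc = origins - c
        b = np.einsum("ni,ni->n", dirs, oc)
        disc = b**2 - (np.einsum("ni,ni->n", oc, oc) - r**2)
        hit = disc >= 0
        sq = np.sqrt(np.maximum(disc, 0))
        t = -b - sq                      # near root
        t_far = -b + sq
        t = np.where(t > 1e-9, t, t_far)  # camera inside sphere: take far root
        valid = hit & (t > 1e-9) & (t < t_best)
        t_best[valid] = t[valid]
        label[valid] = j
    return t_best, label


def render_depth_scan(bunch: BunchModel, pose: CameraPose,
                      artifact: ArtifactModel, pixel_pitch: float = 0.0009,
                      seed: int = 0) -> PointCloud:
    """Render a single-viewpoint depth scan with the artifact chain applied.

    One ray is cast per angular grid cell (``pixel_pitch`` radians); the first
    sphere intersection wins (occlusion-correct).  The artifact stages run in
    the fixed order scatter -> valley smoothing -> quantisation -> dropout ->
    flying pixels -> noise, all deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    centers, radii = bunch.centers(), bunch.radii()
    u, v, w = pose.basis()
    rel = centers - pose.origin
    depth_c = rel @ w
    if np.any(depth_c <= 0):
        raise ValueError("bunch must be in front of the camera (+Z side)")
    # angular grid (tangent coordinates) covering every berry plus a margin
    a_c = (rel @ u) / depth_c
    b_c = (rel @ v) / depth_c
    half = (radii + 2.0) / depth_c
    a_lo, a_hi = float(np.min(a_c - half)), float(np.max(a_c + half))
    b_lo, b_hi = float(np.min(b_c - half)), float(np.max(b_c + half))
    na = max(int(np.ceil((a_hi - a_lo) / pixel_pitch)), 1)
    nb = max(int(np.ceil((b_hi - b_lo) / pixel_pitch)), 1)
    aa = a_lo + pixel_pitch * (np.arange(na) + 0.5)
    bb = b_lo + pixel_pitch * (np.arange(nb) + 0.5)
    A, B = np.meshgrid(aa, bb, indexing="xy")      # (nb, na)
    dirs = (w[None, :] + A.reshape(-1, 1) * u[None, :] + B.reshape(-1, 1) * v[None, :])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    origins = np.broadcast_to(pose.origin, dirs.shape)

    t, label = _first_hit(origins, dirs, centers, radii)
    shape = A.shape
    t_img = t.reshape(shape)
    label_img = label.reshape(shape)
    valid = np.isfinite(t_img)
    if not np.any(valid):
        return PointCloud(points=np.empty((0, 3)), source_tag=artifact.technology)

    standoff = pose.standoff_mm

    # (1) subsurface-scattering displacement
    if artifact.scatters:
        pts = pose.origin + t.reshape(-1, 1) * dirs
        cos_theta = np.zeros(pts.shape[0])
        for j, c in enumerate(centers):
            m = label == j
            if not np.any(m):
                continue
            wvec = pts[m] - c
            wvec /= np.linalg.norm(wvec, axis=1, keepdims=True)
            pole = pose.origin - c
            pole = pole / np.linalg.norm(pole)
            cos_theta[m] = wvec @ pole
        delta = _scatter_displacement_mm(cos_theta, standoff, artifact)
        t_img = (t + np.where(label >= 0, delta, 0.0)).reshape(shape)

    # (2) valley smoothing (normalised convolution over valid pixels)
    if artifact.valley_sigma_mm > 0:
        sigma_px = artifact.valley_sigma_mm / (pixel_pitch * standoff)
        filled = np.where(valid, t_img, 0.0)
        num = gaussian_filter(filled, sigma_px, mode="nearest")
        den = gaussian_filter(valid.astype(float), sigma_px, mode="nearest")
        sm = np.where(den > 1e-9, num / np.maximum(den, 1e-9), t_img)
        t_img = np.where(valid, sm, t_img)

    # (3) depth quantisation
    if artifact.quantisation_step_mm > 0:
        step = artifact.quantisation_step_mm
        t_img = np.where(valid, np.round(t_img / step) * step, t_img)

    # (4) dropout, biased toward inter-berry valleys (locally deep pixels)
    drop_mask = np.zeros(shape, dtype=bool)
    if artifact.dropout_fraction > 0:
        mean_r = float(np.mean(radii))
        sigma_px = max(mean_r / (pixel_pitch * standoff) / 2.0, 1.0)
        filled = np.where(valid, t_img, 0.0)
        num = gaussian_filter(filled, sigma_px, mode="nearest")
        den = gaussian_filter(valid.astype(float), sigma_px, mode="nearest")
        local = np.where(den > 1e-9, num / np.maximum(den, 1e-9), 0.0)
        concavity = np.where(valid, np.maximum(t_img - local, 0.0), 0.0)
        weight = (concavity**2 + 0.05)[valid]
        n_valid = int(valid.sum())
        n_drop = int(round(artifact.dropout_fraction * n_valid))
        if n_drop > 0:
            p = weight / weight.sum()
            chosen = rng.choice(n_valid, size=min(n_drop, n_valid), replace=False, p=p)
            flat = np.zeros(n_valid, dtype=bool)
            flat[chosen] = True
            drop_mask[valid] = flat

    # (5) flying pixels at silhouette edges (gap between two surfaces)
    if artifact.flying_pixel_rate > 0:
        pad = np.pad(t_img, 1, constant_values=np.nan)
        vpad = np.pad(valid, 1, constant_values=False)
        best_gap = np.zeros(shape)
        partner = np.full(shape, np.nan)
        for di, dj in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            nb_t = pad[1 + di : 1 + di + shape[0], 1 + dj : 1 + dj + shape[1]]
            nb_v = vpad[1 + di : 1 + di + shape[0], 1 + dj : 1 + dj + shape[1]]
            both = valid & nb_v
            nb_t = np.where(nb_v, nb_t, 0.0)
            gap = np.where(both, np.abs(np.where(valid, t_img, 0.0) - nb_t), 0.0)
            better = gap > best_gap
            best_gap = np.where(better, gap, best_gap)
            partner = np.where(better, nb_t, partner)
        edge = valid & (best_gap > FLYING_PIXEL_GAP_MM)
        fly = edge & (rng.random(shape) < artifact.flying_pixel_rate)
        if np.any(fly):
            lo = np.minimum(t_img[fly], partner[fly])
            hi = np.maximum(t_img[fly], partner[fly])
            t_img[fly] = rng.uniform(lo, hi)

    keep = valid & ~drop_mask
    t_flat = t_img.reshape(-1)[keep.reshape(-1)]
    d_flat = dirs[keep.reshape(-1)]
    points = pose.origin + t_flat[:, None] * d_flat
    labels = label_img.reshape(-1)[keep.reshape(-1)]

    # (6) isotropic sensor noise
    if artifact.noise_sd_mm > 0:
        points = points + rng.normal(scale=artifact.noise_sd_mm, size=points.shape)

    return PointCloud(points=points, labels=labels, source_tag=artifact.technology)


def chequerboard_landmarks(n_points: int = 12,
                           transform: Optional[RigidTransform] = None,
                           noise_sd_mm: float = 0.0,
                           seed: int = 0) -> tuple:
    """Paired landmark sets (Y, X) emulating chequerboard corner picks.

    Y are chequerboard corners in the reference frame (a planar grid beside
    the bunch, guaranteed non-collinear by construction); X is
    ``transform^-1`` applied to Y plus isotropic noise, so
    ``landmark_align(X, Y)`` recovers ``transform``.
    """
    if n_points < 3:
        raise ValueError("need at least 3 landmarks")
    transform = transform if transform is not None else RigidTransform.identity()
    rng = np.random.default_rng(seed)
    ncols = int(np.ceil(np.sqrt(n_points)))
    ncols = max(ncols, 2)
    spacing = 30.0
    pts = []
    for i in range(n_points):
        r, c = divmod(i, ncols)
        pts.append([(-120.0) + c * spacing, (-60.0) + r * spacing, 700.0])
    Y = np.asarray(pts, dtype=float)
    # a grid with >= 2 columns and >= 3 points is never collinear
    X = transform.inverse().apply(Y)
    if noise_sd_mm > 0:
        X = X + rng.normal(scale=noise_sd_mm, size=X.shape)
    return (PointCloud(points=Y, source_tag="chequerboard/reference"),
            PointCloud(points=X, source_tag="chequerboard/camera"))
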
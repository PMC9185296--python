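"""End-to-end benchmark: simulate -> preprocess -> align -> errors -> detect -> match.

:func:`run_benchmark` reproduces, per camera technology, the full evaluation
chain on a synthetic bunch: render reference and depth scans, perturb the
scan by a seeded rigid misalignment (the two instruments never share a
frame), recover the alignment from chequerboard landmarks, clean
flying-pixel-prone scans, and compute the error map; then the ICP variant
(crop -> projective scale -> ICP); then missing area; then the RANSAC
berry-sizing pipeline.  A single top-level seed fans out to fixed per-stage
child seeds so each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from berrycloud.alignment import (
    RigidTransform,
    apply_transform,
    icp_align,
    landmark_align,
    projective_scale,
    scale_about_origin,
)
from berrycloud.detection import match_spheres, ransac_detect_spheres, sphere_match_stats
from berrycloud.errors import (
    ecdf,
    mean_error,
    missing_area_fraction,
    nearest_point_errors,
    quantile,
    signed_depth_errors,
)
from berrycloud.pointcloud import BoundingBox, PointCloud, crop_box, estimate_normals, write_point_cloud
from berrycloud.preprocess import normal_angle_filter, statistical_outlier_removal
from berrycloud.synthetic import (
    BunchConfig,
    CameraPose,
    generate_bunch,
    preset,
    render_depth_scan,
    render_reference_scan,
    TECHNOLOGIES,
)

logger = logging.getLogger(__name__)

__all__ = ["BenchmarkConfig", "BenchmarkReport", "run_benchmark"]

REPORT_SCHEMA_VERSION = 1

#: technologies whose raw scans carry flying pixels / need cleaning
PREPROCESSED_TECHNOLOGIES = ("tof", "lidar", "active_stereo")


@dataclass
class BenchmarkConfig:
    """Scene, artifact and analysis parameters for one benchmark run."""

    scene: BunchConfig = field(default_factory=BunchConfig)
    technologies: tuple = ("reference", "structured_light", "active_stereo", "tof", "lidar")
    painted: bool = False
    reference_density: float = 1.0
    pixel_pitch: float = 0.0009
    #: seeded rigid misalignment applied to each scan before re-alignment
    misalign_rot_deg: float = 4.0
    misalign_trans_mm: float = 15.0
    n_landmarks: int = 12
    landmark_noise_mm: float = 0.2
    normals_k: int = 16
    max_angle_deg: float = 85.0
    sor_k: int = 6
    sor_nsigma: float = 1.0
    icp_max_iterations: int = 50
    icp_rms_tolerance_mm: float = 1e-3
    crop_margin_mm: float = 5.0
    image_size: int = 96
    ransac_epsilon_mm: float = 1.5
    ransac_min_support: int = 30
    ransac_max_radius_mm: float = 20.0
    ransac_max_iterations: int = 400

    def validate(self) -> None:
        for tech in self.technologies:
            if tech not in TECHNOLOGIES:
                raise ValueError(f"config error at key 'technologies': unknown technology {tech!r}")
        for key in ("reference_density", "pixel_pitch", "image_size",
                    "ransac_epsilon_mm", "icp_max_iterations"):
            if getattr(self, key) <= 0:
                raise ValueError(f"config error at key {key!r}: must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        d = dict(d)
        scene = d.pop("scene", {})
        known = {f.name for f in dataclasses.fields(cls)}
        for k in d:
            if k not in known:
                raise ValueError(f"config error at key {k!r}: unknown key")
        scene_known = {f.name for f in dataclasses.fields(BunchConfig)}
        for k in scene:
            if k not in scene_known:
                raise ValueError(f"config error at key 'scene.{k}': unknown key")
        cfg = cls(scene=BunchConfig(**scene), **d)
        if isinstance(cfg.technologies, list):
            cfg.technologies = tuple(cfg.technologies)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["technologies"] = list(self.technologies)
        d["scene"]["center"] = list(self.scene.center)
        return d


@dataclass
class BenchmarkReport:
    records: dict
    seed: int
    config_hash: str
    package_version: str
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), indent=2, **kw)


def _child_seed(seed: int, stage: int, tech_index: int = 0) -> int:
    return (seed * 100003 + stage * 1009 + tech_index * 13) % (2**31 - 1)


def _random_misalignment(rng: np.random.Generator, rot_deg: float, trans_mm: float) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rot_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    t = rng.normal(size=3)
    t = trans_mm * t / np.linalg.norm(t)
    return RigidTransform(R, t)


def run_benchmark(config: Optional[BenchmarkConfig] = None, seed: int = 0,
                  out_dir: Optional[str] = None) -> BenchmarkReport:
    """Execute the full benchmark chain for every configured technology.

    Deterministic for a fixed seed.  When ``out_dir`` is given, per-stage
    artefacts (reference/scan PLYs, ground-truth sphere CSV, report JSON) are
    written there.
    """
    from berrycloud.synthetic import chequerboard_landmarks  # local to avoid cycle at import time
    import berrycloud

    config = config or BenchmarkConfig()
    config.validate()
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

    bunch = generate_bunch(config.scene, seed=_child_seed(seed, 1))
    reference = render_reference_scan(bunch, density=config.reference_density,
                                      seed=_child_seed(seed, 2))
    camera_origin = np.zeros(3)
    pose = CameraPose(origin=camera_origin, look_at=bunch.centroid)

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        write_point_cloud(reference, os.path.join(out_dir, "reference.ply"))
        import pandas as pd
        pd.DataFrame({
            "berry_id": np.arange(len(bunch.berries)),
            "cx": bunch.centers()[:, 0], "cy": bunch.centers()[:, 1],
            "cz": bunch.centers()[:, 2], "radius_mm": bunch.radii(),
        }).to_csv(os.path.join(out_dir, "ground_truth_spheres.csv"), index=False)

    records: dict = {}
    for ti, tech in enumerate(config.technologies):
        logger.info("benchmark stage: technology=%s", tech)
        artifact = preset(tech, painted=config.painted)
        scan = render_depth_scan(bunch, pose, artifact, pixel_pitch=config.pixel_pitch,
                                 seed=_child_seed(seed, 3, ti))
        # the camera and reference scans never share a coordinate frame:
        # perturb by a seeded rigid misalignment, then realign from landmarks
        rng = np.random.default_rng(_child_seed(seed, 4, ti))
        M = _random_misalignment(rng, config.misalign_rot_deg, config.misalign_trans_mm)
        scan_mis = apply_transform(scan, M)
        origin_mis = M.apply(camera_origin[None, :])[0]

        if tech in PREPROCESSED_TECHNOLOGIES and len(scan_mis) > config.normals_k:
            cleaned = estimate_normals(scan_mis, k=config.normals_k, view_origin=origin_mis)
            cleaned = normal_angle_filter(cleaned, view_origin=origin_mis,
                                          max_angle_deg=config.max_angle_deg)
            cleaned = statistical_outlier_removal(cleaned, k=config.sor_k,
                                                  nsigma=config.sor_nsigma)
        else:
            cleaned = scan_mis

        Y, X = chequerboard_landmarks(config.n_landmarks, transform=M.inverse(),
                                      noise_sd_mm=config.landmark_noise_mm,
                                      seed=_child_seed(seed, 5, ti))
        t_hat = landmark_align(X, Y)
        aligned = apply_transform(cleaned, t_hat)

        emap = nearest_point_errors(aligned, reference)
        curve = ecdf(emap)
        signed = signed_depth_errors(aligned, reference, camera_origin)

        # ICP variant: crop -> projective scale -> ICP (landmark pose as start)
        box = BoundingBox.of(reference, margin=config.crop_margin_mm)
        scan_crop = crop_box(aligned, box)
        ref_crop = crop_box(reference, box)
        if len(scan_crop) >= 3:
            s = projective_scale(scan_crop, ref_crop, camera_origin)
            icp = icp_align(scan_crop, ref_crop,
                            max_iterations=config.icp_max_iterations,
                            rms_tolerance_mm=config.icp_rms_tolerance_mm,
                            init=scale_about_origin(s, camera_origin))
            aligned_icp = apply_transform(scan_crop, icp.transform)
            mean_icp = mean_error(nearest_point_errors(aligned_icp, reference))
            icp_converged = icp.converged
        else:
            aligned_icp = aligned
            mean_icp = float("nan")
            icp_converged = False

        missing = missing_area_fraction(aligned, reference, pose, config.image_size)

        # berry sizing uses the most accurately registered cloud: the
        # ICP-refined, projective-scale-corrected scan (the scale correction
        # removes the lateral magnification a depth bias induces, which would
        # otherwise mask the distortion-driven radius underestimation)
        segments = ransac_detect_spheres(
            aligned_icp, epsilon_mm=config.ransac_epsilon_mm,
            min_support=config.ransac_min_support,
            max_radius_mm=config.ransac_max_radius_mm,
            max_iterations=config.ransac_max_iterations,
            seed=_child_seed(seed, 6, ti))
        matches = match_spheres([s.sphere for s in segments], bunch.berries)
        stats = sphere_match_stats(matches, config.ransac_max_radius_mm)

        records[tech] = {
            "n_scan_points": int(len(aligned)),
            "mean_error_landmark_mm": mean_error(emap),
            "mean_signed_depth_error_mm": float(np.mean(signed)),
            "mean_error_icp_mm": mean_icp,
            "icp_converged": bool(icp_converged),
            "missing_area_pct": missing,
            "ecdf_quantiles": {"q50": quantile(curve, 0.5), "q95": quantile(curve, 0.95)},
            "n_spheres": stats.count,
            "median_radius_diff_mm": stats.median_radius_diff_mm,
            "median_position_diff_2d_mm": stats.median_position_diff_2d_mm,
        }
        if out_dir:
            write_point_cloud(scan, os.path.join(out_dir, f"scan_{tech}.ply"))

    report = BenchmarkReport(records=records, seed=seed, config_hash=cfg_hash,
                             package_version=berrycloud.__version__)
    if out_dir:
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
    return report
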
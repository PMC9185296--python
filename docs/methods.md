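# Methods

## Scene model

A grape bunch is modelled as `n` near-spherical berries attached around a
vertical rachis axis. Berry radii are drawn from a truncated normal
distribution (mean 13.7 mm, sd 1.5 mm, truncated to 10–18 mm — the scale of
table grapes measured on dense reference scans). Centres are placed by
rejection sampling inside a cylinder (default radius 34 mm, length 140 mm)
around the axis; a candidate is accepted when it interpenetrates every
previously placed berry by at most 40% of the smaller radius, so berries
touch and slightly squash as in a real bunch. A single-berry bunch sits
exactly at the cluster centre. Generation fails loudly when the packing
constraint cannot be met. The default scene (30 berries, bunch centred
600 mm in front of the camera) reflects a practical scanning distance for a
camera mounted on a vineyard vehicle.

Coordinates are millimetres in the camera frame: origin at the optical
centre, +Z the depth axis.

## Reference scan

The stand-in for a multi-view photogrammetry reconstruction is a uniform
surface sampling of the union of spheres (default 1 point/mm²), with points
buried inside a neighbouring berry removed and each point labelled with its
owning berry. It is exact (zero distance to the analytic surface) and
full-surround — like photogrammetry, it sees parts of the bunch a
single-viewpoint camera cannot.

## Depth-camera model

A depth scan casts one ray per angular grid cell (default pitch 0.9 mrad,
≈ 0.54 mm at 600 mm) from the camera origin and keeps the first
ray–sphere intersection. Artifacts are then applied in a fixed order —
physical effects before sampling effects before sensor noise:

1. **Subsurface scattering** (ToF/LiDAR, unless painted). Each point moves
   along its viewing ray away from the camera by
   `Δ(θ, D) = b + a·(D_ref/D)·cosᵖθ`, where `θ` is the angle at the berry
   centre from the camera-facing pole and `D` the standoff. The constant
   `b` is the depth bias; the second term is the pole-peaked distortion
   that makes each berry look pointed, growing as the camera approaches
   (`D_ref` = 350 mm, the distance at which `a` applies).
2. **Valley smoothing** (active stereo): Gaussian smoothing of the depth
   image (σ in mm, converted to pixels at the scene standoff) via
   normalised convolution over valid pixels.
3. **Quantisation**: depth rounded to the nearest step.
4. **Dropout** (structured light): a fixed fraction of points removed, with
   probability proportional to squared local concavity (depth minus a
   berry-scale smoothed depth), so losses concentrate in the inter-berry
   valleys the projector cannot illuminate.
5. **Flying pixels**: where a grid neighbour's depth differs by more than
   5 mm (larger than any quantisation step, smaller than a berry), the
   point is displaced, with a preset probability, to a uniform depth
   between the two surfaces.
6. **Isotropic Gaussian noise**.

All stages are deterministic given a seed. `painted=True` zeroes the
effective bias and distortion only — modelling an opaque coating that stops
light entering the berry — while sampling artifacts persist.

### Preset parameters

| preset | bias (mm) | distortion a, p | quant (mm) | valley σ (mm) | dropout | flying | noise (mm) |
|---|---|---|---|---|---|---|---|
| reference | 0 | – | 0 | 0 | 0 | 0 | 0 |
| structured_light | 0 | – | 7.0 | 0 | 0.60 | 0 | 0.5 |
| active_stereo | 0 | – | 0 | 2.5 | 0 | 0 | 0.3 |
| tof | 7.0 | 2.5, 12 | 2.0 | 0 | 0 | 0.10 | 1.0 |
| lidar | 8.5 | 2.0, 12 | 0 | 0 | 0 | 0.03 | 1.0 |

Rationale for the non-obvious choices:

* **Bias values** (7 mm ToF, 8.5 mm LiDAR) are the painted-vs-unpainted peak
  displacements reported for single berries at 350 mm with cameras of these
  technologies.
* **Distortion split.** Measurements of the scattering effect never separate
  a mean bias from a peak amplitude, so the split is a modelling choice. We
  keep the distortion term sharply localised (p = 12) with a small
  amplitude, so the bunch-averaged along-ray displacement is dominated by
  the bias (the projected-area average of cosᵖθ is 2/(p+2) ≈ 0.14, i.e.
  ≈ 0.2–0.3 mm), while the apex still stands well proud of the local sphere
  (a·p/r > 1, a visibly pointed profile in cross-section). A broader peak
  would make the measured "bias" standoff-dependent and inconsistent with
  its quoted value.
* **Structured-light dropout** (0.60) was calibrated once, on the default
  scene, so the rendered preset loses about 20% of its projected silhouette
  area relative to the reference — the missing-area figure characteristic of
  this camera class, whose projected pattern cannot resolve the inter-berry
  valleys. The large quantisation step (7 mm) reflects the coarse
  depth-resolution of first-generation structured-light devices at 600 mm.
* **Noise** values (0.3–1.0 mm) are typical per-point depth noise for the
  respective device classes at this range.

## Registration

* `landmark_align` solves `argmin_{R,T} Σᵢ‖Yᵢ − R·Xᵢ − T‖²` in closed form
  (SVD of the centred cross-covariance, determinant-corrected so a
  reflection is never returned). Chequerboard landmark pairs exercise it in
  simulation: the benchmark applies a seeded rigid misalignment to each
  scan — the two instruments never share a frame — and recovers it from
  noisy landmarks.
* `icp_align` is point-to-point ICP: exact nearest-neighbour
  correspondences (KD-tree), closed-form re-solve, iterated until the
  matched RMS changes by < 1e-3 mm or 50 iterations. The RMS is
  non-increasing by construction. Scale is never optimised inside ICP.
* `projective_scale` corrects a scan that sits behind the reference because
  of a depth bias: displacing points along their viewing rays is, to first
  order, a radial magnification about the optical centre, so a uniform
  scale about the camera undoes it. The factor is the median ratio of
  reference to source range, matched *along viewing directions* and taking
  the closest-range (camera-facing) candidate on each side, which keeps the
  estimate exact for along-ray displacement and well-defined against a
  full-surround reference (whose overall median range lies behind the
  visible shell).

## Error statistics

The primary error map is the unsigned exact nearest-point distance to the
reference cloud, summarised by its mean and ECDF quantiles. Because a depth
bias has a sign, a separate statistic reports the signed along-ray error:
each scan point is compared with the reference point nearest in viewing
direction (taking the minimum range among the nearest directions, i.e. the
camera-facing surface). With a dense reference this recovers along-ray
displacement directly; the unsigned metric underestimates it at oblique
incidence, which is why the measured unsigned means (≈ 4–4.5 mm for the
biased presets) sit below the 7–8.5 mm biases.

Missing scan area rasterises both clouds by perspective projection onto a
common grid framed on the reference silhouette (5% margin), marks a pixel
covered when at least one point lands in it, applies a 1-pixel morphological
closing to bridge sampling pinholes, and reports the coverage difference in
percent of the image. The default raster (96×96) puts one pixel at roughly
one ray spacing of the default scan; a much finer raster would turn point
sampling itself into spurious "missing area" that a fixed 1-pixel closing
cannot bridge.

## Berry detection

Greedy sequential RANSAC: draw a seed point uniformly, draw the three
remaining sample points from its neighbourhood (1.5 × the maximum plausible
radius — a fully global 4-point draw almost never lands on a single berry
when thirty are present), solve the exact 4-point sphere (rejecting
near-coplanar quadruples), and count inliers within ε = 1.5 mm of the
surface. After 400 hypotheses the best candidate is kept if it has ≥ 30
supporting points and radius ≤ 20 mm; its inlier set is restricted to the
connected component (3 mm linkage) around the sample seed — candidate
spheres otherwise graze neighbouring berries and inflate on refit — then
refined by an algebraic least-squares fit, removed, and the process
repeats. A round whose winning candidate collapses under component
filtering is retried with fresh samples (at most five consecutive
failures). ε, support and iteration count were fixed after one calibration
pass on the default reference-preset scene.

Detected spheres are matched to the nearest reference berry centre in full
3D (many-to-one allowed); reported position differences exclude the depth
axis so they are not dominated by any distance bias, and summary medians
ignore detected spheres over 20 mm radius. In the pipeline, detection runs
on the ICP-refined, projective-scale-corrected cloud: the scale correction
removes the ≈ r·b/D lateral magnification that a depth bias induces, which
would otherwise mask the distortion-driven radius underestimation of the
scattering presets. The benchmark matches against the generator's
ground-truth spheres rather than spheres re-fitted to the reference render;
the reference render is exact, so the two differ only by sampling noise
(≲ 0.05 mm).

## What the simulation does and does not show

The generator reproduces the artifact *classes* and their measured scales —
not device physics. Passing tests demonstrate that the pipeline recovers
planted biases, calibrated missing areas, and the direction of
distortion-induced sizing errors from data with known ground truth. They do
not validate radiometric behaviour, leaf/stem occlusion, sunlight saturation
(represented only as preset noise/dropout levels), ellipsoidal berries, or
photogrammetric reconstruction error (the reference here is exact; a real
photogrammetry scan smooths inter-berry valleys slightly). The magnitude of
the median radius underestimation for the scattering presets (≈ −0.3 to
−1 mm) is smaller than reported for real ToF/LiDAR scans of grapes
(−3 to −3.7 mm), a direct consequence of keeping the distortion's
bunch-average inside the quoted bias figure; the sign and the contrast with
the non-scattering presets are reproduced.

## Numerical choices and degenerate inputs

* All neighbour queries are exact KD-tree queries, contractually equal to
  brute force.
* Normal estimation flags neighbourhoods whose covariance is rank < 2
  (duplicated points) and assigns a viewer-facing sentinel normal with a
  logged warning instead of raising.
* The algebraic sphere fit centres its input before solving, rejects
  configurations whose design matrix is rank-deficient (relative singular
  value < 1e-8), and is exact on noiseless spheres including the minimal
  4-point case.
* Landmark alignment raises on < 3 or collinear landmarks (second singular
  value ≤ 1e-9 relative).
* Binary PLY is rejected with an explicit error; parse errors name the
  offending line.
* ECDF quantiles are right-continuous (smallest value with cumulative
  fraction ≥ q); even-count medians average the central pair.
* Benchmark child seeds derive from the top seed by fixed affine offsets
  (modulo 2³¹−1) so each stage is independently reproducible.

## Problem sizes

The default benchmark uses a 30-berry bunch, a ~60 k-point reference render
and ~30 k-point scans, chosen so the full five-technology benchmark
completes in well under a minute on one CPU while keeping several hundred
points per visible berry for stable sphere fits. Orchestration tests use a
scaled-down scene (8–12 berries, coarser ray grid), which carries
proportionally more raster discretisation in the missing-area statistic.
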
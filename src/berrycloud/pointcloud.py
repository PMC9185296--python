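"""Point-cloud data model, ASCII PLY / XYZ I/O, cropping and normal estimation.

Conventions used throughout the package:

* coordinates are **millimetres** in the camera frame — origin at the camera
  optical centre, +Z along the viewing axis (depth);
* PLY files are ASCII only, with float properties ``x, y, z`` and optionally
  ``nx, ny, nz``; binary PLY is rejected with a clear error;
* all nearest-neighbour queries are exact (KD-tree backed, equal to brute
  force), never approximate.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from io import StringIO
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "PointCloud",
    "BoundingBox",
    "ParseError",
    "read_point_cloud",
    "write_point_cloud",
    "crop_box",
    "estimate_normals",
]


class ParseError(ValueError):
    """Malformed point-cloud file (message names the offending line)."""


@dataclass
class PointCloud:
    """N points in millimetres, camera frame, with optional normals and labels.

    Parameters
    ----------
    points
        ``(N, 3)`` float array of coordinates.
    normals
        Optional ``(N, 3)`` array of unit normals.
    labels
        Optional ``(N,)`` integer array of segment ids (e.g. owning berry).
    source_tag
        Free-text provenance tag (camera technology, file name, ...).
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if self.normals.shape[0] != self.points.shape[0]:
                raise ValueError("normals must match point count")
            norms = np.linalg.norm(self.normals, axis=1)
            if self.normals.shape[0] and np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("normals must be unit length (within 1e-6)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
            if self.labels.shape[0] != self.points.shape[0]:
                raise ValueError("labels must match point count")

    def __len__(self) -> int:
        return self.points.shape[0]

    def select(self, index: np.ndarray, source_tag: Optional[str] = None) -> "PointCloud":
        """Subset by integer or boolean index, carrying normals/labels through."""
        return PointCloud(
            points=self.points[index],
            normals=None if self.normals is None else self.normals[index],
            labels=None if self.labels is None else self.labels[index],
            source_tag=self.source_tag if source_tag is None else source_tag,
        )


@dataclass
class BoundingBox:
    """Axis-aligned box in millimetres; closed interval on every axis."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        self.min_corner = np.asarray(self.min_corner, dtype=float).reshape(3)
        self.max_corner = np.asarray(self.max_corner, dtype=float).reshape(3)
        if np.any(self.min_corner > self.max_corner):
            raise ValueError("min_corner must be <= max_corner componentwise")

    @classmethod
    def of(cls, cloud: PointCloud, margin: float = 0.0) -> "BoundingBox":
        if len(cloud) == 0:
            raise ValueError("cannot take bounding box of empty cloud")
        return cls(cloud.points.min(axis=0) - margin, cloud.points.max(axis=0) + margin)


def _parse_table(text: str, n_expected: Optional[int], n_cols: int, first_line: int, path: str) -> np.ndarray:
    """Parse whitespace-delimited float rows; name the bad line on failure."""
    if not text.strip():
        if n_expected:
            raise ParseError(f"{path}: header declares {n_expected} vertices but 0 rows found")
        return np.empty((0, n_cols))
    try:
        data = np.loadtxt(StringIO(text), ndmin=2)
    except ValueError:
        for i, line in enumerate(text.splitlines()):
            if not line.strip():
                continue
            try:
                [float(v) for v in line.split()]
            except ValueError:
                raise ParseError(f"{path}: cannot parse line {first_line + i}: {line!r}") from None
        raise ParseError(f"{path}: malformed numeric data") from None
    if data.size == 0:
        data = np.empty((0, n_cols))
    if data.shape[1] < n_cols:
        raise ParseError(f"{path}: expected at least {n_cols} columns, found {data.shape[1]}")
    if n_expected is not None and data.shape[0] != n_expected:
        raise ParseError(
            f"{path}: header declares {n_expected} vertices but {data.shape[0]} rows found"
        )
    return data


def _read_ply(path: str) -> PointCloud:
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError(f"{path}: line 1: not a PLY file (missing 'ply' magic)")
    n_vertex = None
    props: list[str] = []
    header_end = None
    in_vertex_element = False
    for i, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if line.startswith("format"):
            if "ascii" not in line:
                raise ParseError(f"{path}: line {i}: only ASCII PLY is supported, got {line!r}")
        elif line.startswith("element"):
            parts = line.split()
            in_vertex_element = len(parts) == 3 and parts[1] == "vertex"
            if in_vertex_element:
                try:
                    n_vertex = int(parts[2])
                except ValueError:
                    raise ParseError(f"{path}: line {i}: bad vertex count {line!r}") from None
        elif line.startswith("property") and in_vertex_element:
            props.append(line.split()[-1])
        elif line == "end_header":
            header_end = i
            break
    if header_end is None or n_vertex is None:
        raise ParseError(f"{path}: incomplete PLY header")
    for name in ("x", "y", "z"):
        if name not in props:
            raise ParseError(f"{path}: vertex element lacks property {name!r}")
    body = "\n".join(lines[header_end : header_end + n_vertex])
    data = _parse_table(body, n_vertex, len(props), header_end + 1, path)
    ix = [props.index(n) for n in ("x", "y", "z")]
    points = data[:, ix]
    normals = None
    if all(n in props for n in ("nx", "ny", "nz")):
        normals = data[:, [props.index(n) for n in ("nx", "ny", "nz")]]
        if normals.shape[0]:
            # guard against drift from limited ASCII precision
            normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(points=points, normals=normals, source_tag=os.path.basename(path))


def _read_xyz(path: str) -> PointCloud:
    with open(path, "r") as fh:
        text = fh.read()
    data = _parse_table(text, None, 3, 1, path)
    return PointCloud(points=data[:, :3], source_tag=os.path.basename(path))


def _infer_format(path: str, format: Optional[str]) -> str:
    if format is not None:
        return format
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("ply", "xyz"):
        return ext
    raise ValueError(f"cannot infer format from {path!r}; pass format='ply' or 'xyz'")


def read_point_cloud(path: str, format: Optional[str] = None) -> PointCloud:
    """Read an ASCII PLY or whitespace-delimited XYZ file (millimetres).

    PLY files must be ASCII with at least float ``x, y, z`` vertex properties;
    ``nx, ny, nz`` are loaded as normals when present.  XYZ files are plain
    whitespace-delimited tables with at least three columns.
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path: str, format: Optional[str] = None) -> None:
    """Write ``cloud`` as ASCII PLY (with normals when present) or XYZ."""
    fmt = _infer_format(path, format)
    if fmt == "ply":
        with_normals = cloud.normals is not None
        header = ["ply", "format ascii 1.0", f"element vertex {len(cloud)}"]
        header += [f"property float {n}" for n in ("x", "y", "z")]
        if with_normals:
            header += [f"property float {n}" for n in ("nx", "ny", "nz")]
        header.append("end_header")
        data = cloud.points if not with_normals else np.hstack([cloud.points, cloud.normals])
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            np.savetxt(fh, data, fmt="%.6f")
    elif fmt == "xyz":
        with open(path, "w") as fh:
            np.savetxt(fh, cloud.points, fmt="%.6f")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def crop_box(cloud: PointCloud, box: BoundingBox) -> PointCloud:
    """Keep exactly the points inside the closed box; order preserved."""
    inside = np.all((cloud.points >= box.min_corner) & (cloud.points <= box.max_corner), axis=1)
    return cloud.select(inside)


def estimate_normals(cloud: PointCloud, k: int = 16, view_origin=(0.0, 0.0, 0.0)) -> PointCloud:
    """Estimate per-point unit normals oriented toward ``view_origin``.

    Each normal is the smallest-eigenvector direction of the covariance of the
    point's ``k`` exact nearest neighbours (the point itself included), flipped
    so that ``dot(normal, view_origin - point) >= 0``.  Degenerate
    neighbourhoods (rank < 2 covariance, e.g. duplicated points) receive a
    sentinel normal toward the viewer and a logged warning rather than an
    exception.
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("k must be >= 3")
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    view_origin = np.asarray(view_origin, dtype=float).reshape(3)
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k)
    nbrs = cloud.points[idx]                      # (N, k, 3)
    centred = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / k
    eigvals, eigvecs = np.linalg.eigh(cov)        # ascending
    normals = eigvecs[:, :, 0]
    # rank < 2: the two smallest eigenvalues both vanish relative to the spread
    scale = np.maximum(eigvals[:, 2], 1e-30)
    degenerate = eigvals[:, 1] / scale < 1e-9
    to_view = view_origin[None, :] - cloud.points
    flip = np.einsum("ni,ni->n", normals, to_view) < 0
    normals[flip] *= -1.0
    if np.any(degenerate):
        logger.warning("estimate_normals: %d degenerate neighbourhoods, using viewer-facing sentinel",
                       int(degenerate.sum()))
        d = to_view[degenerate]
        lens = np.linalg.norm(d, axis=1, keepdims=True)
        lens[lens == 0] = 1.0
        normals[degenerate] = d / lens
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(points=cloud.points.copy(), normals=normals,
                      labels=None if cloud.labels is None else cloud.labels.copy(),
                      source_tag=cloud.source_tag)
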
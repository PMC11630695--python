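"""Labeled 3D point clouds and their PLY/CSV serialization.

A :class:`PointCloud3D` holds the surface points of one bone at one posture,
in millimetres, expressed in the intrinsic wing frame.  PLY files are ASCII
with ``x``/``y``/``z`` vertex properties; CSV files carry a
``x_mm,y_mm,z_mm`` header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import EmptyInputError, IllPosedFitError

POSTURES = ("extension", "half_extension", "flexion")


@dataclass(frozen=True)
class PointCloud3D:
    """An ordered set of 3D points (mm) for one bone at one posture."""

    points: np.ndarray
    bone: str = ""
    posture: str = ""

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("point coordinates must be finite")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise EmptyInputError("empty cloud has no centroid")
        return self.points.mean(axis=0)

    def centered_rank(self, tol: float = 1e-9) -> int:
        """Rank of the mean-centered coordinates (3 for a non-coplanar cloud)."""
        c = self.points - self.points.mean(axis=0)
        s = np.linalg.svd(c, compute_uv=False)
        scale = s[0] if s.size and s[0] > 0 else 1.0
        return int(np.sum(s > tol * max(scale, 1.0)))

    def require_well_posed(self) -> "PointCloud3D":
        """Raise unless the cloud can anchor a unique rigid fit."""
        if len(self) < 4:
            raise IllPosedFitError(
                f"cloud '{self.bone}/{self.posture}' has {len(self)} points; >= 4 required"
            )
        if self.centered_rank() < 3:
            raise IllPosedFitError(
                f"cloud '{self.bone}/{self.posture}' is rank-deficient (coplanar or collinear)"
            )
        return self

    def with_points(self, points: np.ndarray) -> "PointCloud3D":
        return PointCloud3D(points, bone=self.bone, posture=self.posture)


def write_ply(cloud: PointCloud3D, path) -> Path:
    path = Path(path)
    pc = trimesh.PointCloud(cloud.points)
    data = trimesh.exchange.ply.export_ply(pc, encoding="ascii")
    path.write_bytes(data if isinstance(data, bytes) else data.encode())
    return path


def read_ply(path, bone: str = "", posture: str = "") -> PointCloud3D:
    loaded = trimesh.load(str(path), process=False)
    pts = np.asarray(loaded.vertices, dtype=float)
    return PointCloud3D(pts, bone=bone, posture=posture)


def write_csv(cloud: PointCloud3D, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(cloud.points, columns=["x_mm", "y_mm", "z_mm"])
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_csv(path, bone: str = "", posture: str = "") -> PointCloud3D:
    df = pd.read_csv(path)
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return PointCloud3D(pts, bone=bone, posture=posture)


def read_cloud(path, bone: str = "", posture: str = "") -> PointCloud3D:
    """Dispatch on extension: .ply or .csv."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return read_ply(path, bone, posture)
    if path.suffix.lower() == ".csv":
        return read_csv(path, bone, posture)
    raise ValueError(f"unsupported cloud format: {path.suffix}")
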
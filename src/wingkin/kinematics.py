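"""Intrinsic wing frame and axis-angle kinematics of the folding wing.

The intrinsic wing skeleton frame sits at the root of the humerus of the
fully extended wing: the y-axis runs along the line joining the leading
points of the humerus and the metacarpal, the z-axis is the normal of the
triangular plane those two points close with the olecranon of the ulna
(oriented dorsally), and x completes the right-handed triad.  All bone
motions are expressed in this frame.

Fitted absolute poses are converted into the relative motions of the
folding chain (ulna and radius on the humerus, carpometacarpus on the ulna,
proximal digit II on the carpometacarpus) and decomposed into principal
axis-angle form; the per-bone report mirrors the measured-kinematics table:
axis and angle at half-extension and at flexion, the axis deviation between
the two postures, and the flexion/half-extension angle ratio (close to 2
for every bone — folding roughly doubles each rotation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFrameError, ReportError
from .geometry import RigidTransform, rotation_to_axis_angle, unit
from .synthetic import BONES, DISPLAY_NAMES, PARENT

REPORT_BONES = ("ulna", "radius", "metacarpus", "digit2")


@dataclass(frozen=True)
class WingFrame:
    """Right-handed orthonormal frame at the humerus root (mm)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), float).reshape(3))
        m = self.matrix()
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-9) or np.linalg.det(m) < 0:
            raise DegenerateFrameError("axes are not right-handed orthonormal")

    def matrix(self) -> np.ndarray:
        """Columns are the frame axes expressed in world coordinates."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self) -> RigidTransform:
        """World → wing-frame coordinates."""
        m = self.matrix().T
        return RigidTransform(m, -m @ self.origin)


def build_wing_frame(humerus_root, humerus_leading, metacarpal_leading,
                     olecranon, up_hint=(0.0, 0.0, 1.0)) -> WingFrame:
    """Construct the intrinsic wing frame from four landmarks.

    y is the unit vector from the humerus leading point to the metacarpal
    leading point; z the unit normal of the (humerus leading, metacarpal
    leading, olecranon) triangle with positive component along ``up_hint``;
    x = y × z, and z is re-orthogonalized as x × y.
    """
    hr = np.asarray(humerus_root, float)
    hl = np.asarray(humerus_leading, float)
    ml = np.asarray(metacarpal_leading, float)
    ol = np.asarray(olecranon, float)

    y = ml - hl
    if np.linalg.norm(y) < 1e-12:
        raise DegenerateFrameError("humerus and metacarpal leading points coincide")
    y = unit(y)
    normal = np.cross(ml - hl, ol - hl)
    if np.linalg.norm(normal) < 1e-9 * max(np.linalg.norm(ml - hl), 1.0):
        raise DegenerateFrameError("wing-plane landmarks are collinear")
    z = unit(normal)
    if np.dot(z, np.asarray(up_hint, float)) < 0:
        z = -z
    x = unit(np.cross(y, z))
    z = np.cross(x, y)
    return WingFrame(hr, x, y, z)


def build_wing_frame_from_landmarks(landmarks: dict,
                                    up_hint=(0.0, 0.0, 1.0)) -> WingFrame:
    """Convenience wrapper taking the named-landmark dict used in manifests."""
    return build_wing_frame(landmarks["humerus_root"], landmarks["humerus_leading"],
                            landmarks["metacarpal_leading"], landmarks["olecranon"],
                            up_hint=up_hint)


def relative_transform(child: RigidTransform, parent: RigidTransform) -> RigidTransform:
    """Motion of the child bone as seen from its (moving) parent: parent⁻¹ ∘ child."""
    return parent.inverse() @ child


def axis_deviation(axis_half, axis_flex) -> float:
    """Percent deviation between the two posture axes: 100·sin(inter-axis angle).

    Symmetric in its arguments and insensitive to axis sign (an axis and its
    negation describe the same rotation line).
    """
    a = unit(axis_half)
    b = unit(axis_flex)
    s = np.linalg.norm(np.cross(a, b))
    return float(100.0 * np.clip(s, 0.0, 1.0))


def _transform_of(entry) -> RigidTransform:
    """Accept a RigidTransform, a FitResult, or a GroundTruthPose."""
    if isinstance(entry, RigidTransform):
        return entry
    if hasattr(entry, "transform"):
        return entry.transform
    raise ReportError(f"cannot extract a transform from {type(entry)!r}")


def relative_motions(fits: dict) -> dict:
    """Per-bone relative motion transforms for both folded postures.

    ``fits`` maps bone → posture → (FitResult | RigidTransform); absolute
    poses in the wing frame.  The chain parent of each report bone must be
    present.
    """
    out = {}
    for bone in REPORT_BONES:
        if bone not in fits:
            raise ReportError(f"no fit supplied for bone '{bone}'")
        parent = PARENT[bone]
        if parent not in fits:
            raise ReportError(f"missing parent fit '{parent}' for bone '{bone}'")
        per_bone = {}
        for posture in ("half_extension", "flexion"):
            if posture not in fits[bone]:
                raise ReportError(f"bone '{bone}' missing posture '{posture}'")
            if posture not in fits[parent]:
                raise ReportError(f"parent '{parent}' missing posture '{posture}'")
            per_bone[posture] = relative_transform(
                _transform_of(fits[bone][posture]),
                _transform_of(fits[parent][posture]))
        out[bone] = per_bone
    return out


def make_report(fits: dict) -> pd.DataFrame:
    """Axis-angle kinematics table, one row per moving bone.

    Columns: bone, axis components and angle at half-extension and flexion,
    axis deviation (percent) between the two posture axes, and the
    flexion/half-extension angle ratio as a folding diagnostic.  Full
    precision is kept; rounding happens only at serialization.
    """
    if not fits:
        raise ReportError("no fits supplied")
    rel = relative_motions(fits)
    rows = []
    for bone in REPORT_BONES:
        aa_half = rotation_to_axis_angle(rel[bone]["half_extension"].rotation)
        aa_flex = rotation_to_axis_angle(rel[bone]["flexion"].rotation)
        dev = axis_deviation(aa_half.axis, aa_flex.axis)
        ratio = (aa_flex.angle_deg / aa_half.angle_deg
                 if aa_half.angle_deg > 1e-9 else np.nan)
        rows.append({
            "bone": DISPLAY_NAMES[bone],
            "axis_half_x": aa_half.axis[0], "axis_half_y": aa_half.axis[1],
            "axis_half_z": aa_half.axis[2], "theta_half_deg": aa_half.angle_deg,
            "axis_flex_x": aa_flex.axis[0], "axis_flex_y": aa_flex.axis[1],
            "axis_flex_z": aa_flex.axis[2], "theta_flex_deg": aa_flex.angle_deg,
            "axis_deviation_pct": dev,
            "flexion_half_ratio": ratio,
        })
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path, config_hash: str | None = None):
    """Serialize the kinematics table, rounded to 2 decimals, as CSV."""
    out = report.copy()
    num = out.select_dtypes(include=[np.number]).columns
    out[num] = out[num].round(2)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        out.to_csv(fh, index=False)
    return path
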
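"""Synthetic falcon wing skeleton: bone-like point clouds under known poses.

The CT scans behind the measured wing kinematics are not publicly deposited,
so every downstream stage (registration, kinematics, mechanism synthesis) is
exercised on synthetic stand-ins: capsule-like bone surfaces with flared
epiphyses and a slight longitudinal bow (both are needed to make all three
rotational degrees of freedom identifiable from shape alone), sampled at the
same per-bone point counts as the original scans, posed by known ground-truth
rigid transforms built from the published axis-angle measurements, with
sub-voxel Gaussian noise and random subsampling so that moving and reference
clouds share no point-to-point correspondence — as real repeated scans do not.

Point counts per bone follow the scans: humerus 9763, ulna 7323, radius 3965,
metacarpus 4901, proximal digit II 1813.  The default noise sigma of 0.2 mm
sits below the 0.625 mm CT slice thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cloud import POSTURES, PointCloud3D, write_csv, write_ply
from .errors import ConfigurationError, InvalidSpecError
from .geometry import RigidTransform, perpendicular_unit, unit

BONES = ("humerus", "ulna", "radius", "metacarpus", "digit2")

DISPLAY_NAMES = {
    "humerus": "Humerus",
    "ulna": "Ulna",
    "radius": "Radius",
    "metacarpus": "Metacarpal",
    "digit2": "Proximal digit II",
}

#: Kinematic chain of the folding wing: each moving bone and its parent.
#: The ulna and radius both articulate on the humerus; the carpometacarpus
#: moves relative to the ulna and proximal digit II relative to the
#: carpometacarpus.  The two carpal bones (radiale, ulnare) are carried as
#: frozen placeholder links: too small to measure at CT resolution.
PARENT = {
    "ulna": "humerus",
    "radius": "humerus",
    "metacarpus": "ulna",
    "digit2": "metacarpus",
}

#: Measured axis-angle motion of the falcon wing bones from full extension,
#: per posture: (axis_x, axis_y, axis_z, angle_deg).  Axes as printed
#: (2-decimal components, renormalized on use).
FALCON_MOTION = {
    "ulna": {
        "half_extension": ((-0.21, -0.17, 0.96), 16.42),
        "flexion": ((-0.31, -0.13, 0.94), 38.83),
    },
    "radius": {
        "half_extension": ((-0.33, -0.31, 0.89), 17.52),
        "flexion": ((-0.33, -0.19, 0.93), 38.89),
    },
    "metacarpus": {
        "half_extension": ((0.28, -0.22, 0.93), 23.44),
        "flexion": ((0.22, -0.11, 0.97), 55.04),
    },
    "digit2": {
        "half_extension": ((-0.01, 0.18, 0.98), 4.84),
        "flexion": ((-0.12, 0.39, 0.91), 10.02),
    },
}

#: Published axis-deviation column (percent), for cross-checking the
#: documented interpretation (100·sin of the inter-axis angle).
FALCON_AXIS_DEVIATION_PCT = {
    "ulna": 11.02,
    "radius": 12.09,
    "metacarpus": 12.66,
    "digit2": 25.32,
}

_DEFAULT_COUNTS = {
    "humerus": 9763,
    "ulna": 7323,
    "radius": 3965,
    "metacarpus": 4901,
    "digit2": 1813,
}

# Peregrine-falcon-scale bone layout in the intrinsic wing frame (mm):
# humerus root at the origin, long axes roughly along +y in full extension,
# radius parallel to and anterior of the ulna.
_DEFAULT_LAYOUT = {
    #           origin            direction   length  radius
    "humerus": ((0.0, 0.0, 0.0), (0.0, 1.0, 0.0), 85.0, 4.0),
    "ulna": ((0.0, 85.0, 0.0), (0.0, 1.0, 0.0), 100.0, 3.0),
    "radius": ((8.0, 85.0, 0.0), (0.0, 1.0, 0.0), 100.0, 2.0),
    "metacarpus": ((2.0, 185.0, 0.0), (0.0, 1.0, 0.0), 55.0, 2.5),
    "digit2": ((2.0, 240.0, 0.0), (0.0, 1.0, 0.0), 30.0, 1.5),
}

#: Landmarks defining the intrinsic wing frame (mm, extension posture):
#: the humerus root (origin), leading points of humerus and metacarpal
#: (their line gives the y-axis), and the olecranon of the ulna closing
#: the triangular wing plane.
DEFAULT_LANDMARKS = {
    "humerus_root": (0.0, 0.0, 0.0),
    "humerus_leading": (6.0, 10.0, 0.0),
    "metacarpal_leading": (6.0, 230.0, 0.0),
    "olecranon": (-6.0, 85.0, 0.0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic bone cloud.

    ``length_mm`` is the overall tip-to-tip bone length including the flared
    end caps; ``radius_mm`` the mid-shaft radius.  ``flare_proximal`` /
    ``flare_distal`` scale the end radii (unequal by default so the two ends
    are distinguishable), and ``bow`` bows the shaft sideways by that
    fraction of the length, breaking the axial spin symmetry a straight
    capsule would have.
    """

    bone_name: str
    n_points: int
    length_mm: float
    radius_mm: float
    noise_sigma_mm: float = 0.2
    overlap_fraction: float = 0.8
    seed: int = 0
    origin: tuple = (0.0, 0.0, 0.0)
    direction: tuple = (0.0, 1.0, 0.0)
    flare_proximal: float = 1.6
    flare_distal: float = 1.9
    bow: float = 0.05

    def __post_init__(self):
        if self.n_points < 4:
            raise InvalidSpecError(f"n_points must be >= 4, got {self.n_points}")
        if self.length_mm <= 0 or self.radius_mm <= 0:
            raise InvalidSpecError("length_mm and radius_mm must be positive")
        if self.noise_sigma_mm < 0:
            raise InvalidSpecError("noise_sigma_mm must be non-negative")
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise InvalidSpecError("overlap_fraction must be in (0, 1]")
        max_flare = max(self.flare_proximal, self.flare_distal)
        if self.length_mm <= 2.0 * max_flare * self.radius_mm:
            raise InvalidSpecError("bone must be longer than its end caps")


def default_specs(noise_sigma_mm: float = 0.2, overlap_fraction: float = 0.8,
                  seed: int = 0, subsample: int = 1) -> dict:
    """Per-bone specs at the scanned point counts (optionally ``subsample``-fold fewer)."""
    specs = {}
    for i, bone in enumerate(BONES):
        origin, direction, length, radius = _DEFAULT_LAYOUT[bone]
        specs[bone] = SyntheticSpec(
            bone_name=bone,
            n_points=max(4, _DEFAULT_COUNTS[bone] // subsample),
            length_mm=length,
            radius_mm=radius,
            noise_sigma_mm=noise_sigma_mm,
            overlap_fraction=overlap_fraction,
            seed=seed * 1009 + i,
            origin=origin,
            direction=direction,
        )
    return specs


def _shaft_frame(direction):
    d = unit(direction)
    n1 = perpendicular_unit(d)
    n2 = np.cross(d, n1)
    return d, n1, n2


def generate_bone_cloud(spec: SyntheticSpec) -> PointCloud3D:
    """Sample ``spec.n_points`` points on a bowed, end-flared capsule surface.

    Deterministic given ``spec.seed``.  Gaussian isotropic noise of sd
    ``noise_sigma_mm`` is added to every coordinate.
    """
    rng = np.random.default_rng(spec.seed)
    d, n1, n2 = _shaft_frame(spec.direction)
    origin = np.asarray(spec.origin, dtype=float)

    r0 = spec.radius_mm
    r_prox = r0 * spec.flare_proximal
    r_dist = r0 * spec.flare_distal
    shaft_len = spec.length_mm - r_prox - r_dist  # tip-to-tip extent == length_mm

    n = spec.n_points
    n_cap_p = max(1, int(round(0.05 * n)))
    n_cap_d = max(1, int(round(0.05 * n)))
    n_shaft = n - n_cap_p - n_cap_d

    # shaft: radius profile flares cubically toward each epiphysis
    t = rng.uniform(0.0, 1.0, n_shaft)
    phi = rng.uniform(0.0, 2.0 * np.pi, n_shaft)
    radius_t = r0 * (1.0
                     + (spec.flare_proximal - 1.0) * (1.0 - t) ** 3
                     + (spec.flare_distal - 1.0) * t ** 3)
    bow_offset = spec.bow * spec.length_mm * np.sin(np.pi * t)
    axial = origin + d * (r_prox + t[:, None] * shaft_len) + n1 * bow_offset[:, None]
    shaft = axial + radius_t[:, None] * (np.cos(phi)[:, None] * n1 + np.sin(phi)[:, None] * n2)

    def hemisphere(center, radius, outward, count):
        v = rng.normal(size=(count, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        flip = (v @ outward) < 0
        v[flip] -= 2.0 * np.outer(v[flip] @ outward, outward)
        return center + radius * v

    cap_p = hemisphere(origin + d * r_prox, r_prox, -d, n_cap_p)
    cap_d = hemisphere(origin + d * (r_prox + shaft_len), r_dist, d, n_cap_d)

    pts = np.vstack([shaft, cap_p, cap_d])
    if spec.noise_sigma_mm > 0:
        pts = pts + rng.normal(scale=spec.noise_sigma_mm, size=pts.shape)
    cloud = PointCloud3D(pts, bone=spec.bone_name, posture="base")
    if cloud.centered_rank() < 3:
        raise InvalidSpecError("generated cloud is degenerate (coplanar)")
    return cloud


@dataclass(frozen=True)
class GroundTruthPose:
    """Known rigid transform of one bone into one posture (extension = identity)."""

    posture: str
    transform: RigidTransform

    def __post_init__(self):
        if self.posture not in POSTURES:
            raise ConfigurationError(f"unknown posture '{self.posture}'")


def make_table1_poses(translations=None) -> dict:
    """Ground-truth *relative* bone motions built from the measured axis-angle rows.

    Returns ``{bone: {posture: GroundTruthPose}}`` for all five bones; the
    humerus (chain root) and every extension entry are the identity.  Axes
    are renormalized to unit length.  Translations default to zero (the
    measurements print none); pass ``{bone: {posture: (tx,ty,tz)}}`` to
    exercise harder recovery problems.
    """
    poses = {}
    for bone in BONES:
        per_bone = {"extension": GroundTruthPose("extension", RigidTransform.identity())}
        for posture in ("half_extension", "flexion"):
            if bone == "humerus":
                tf = RigidTransform.identity()
            else:
                axis, angle = FALCON_MOTION[bone][posture]
                t = None
                if translations is not None:
                    t = translations.get(bone, {}).get(posture)
                tf = RigidTransform.from_axis_angle(unit(axis), angle, translation=t)
            per_bone[posture] = GroundTruthPose(posture, tf)
        poses[bone] = per_bone
    return poses


def compose_chain(relative_poses: dict) -> dict:
    """Absolute pose of each bone in the wing frame from the chain of relative motions.

    ``T_child_abs = T_parent_abs ∘ T_child_rel`` along humerus → {ulna,
    radius} → metacarpus → digit II.
    """
    absolute = {}
    for bone in BONES:  # BONES is in parent-before-child order
        per_bone = {}
        for posture, gt in relative_poses[bone].items():
            if bone in PARENT:
                parent_tf = absolute[PARENT[bone]][posture].transform
                tf = parent_tf @ gt.transform
            else:
                tf = gt.transform
            per_bone[posture] = GroundTruthPose(posture, tf)
        absolute[bone] = per_bone
    return absolute


def pose_clouds(clouds: dict, poses: dict, overlap_fraction: float = 0.8,
                seed: int = 0) -> dict:
    """Build per-posture clouds: random subsample, then the posture transform.

    Each posture cloud is an independent random subsample of
    ``round(overlap_fraction * n)`` base points mapped through that posture's
    (absolute) transform, so clouds of different postures share no
    correspondence.  With ``overlap_fraction == 1`` the base point order is
    preserved.  Deterministic given ``seed``.
    """
    if not (0.0 < overlap_fraction <= 1.0):
        raise InvalidSpecError("overlap_fraction must be in (0, 1]")
    out = {}
    for bi, (bone, cloud) in enumerate(sorted(clouds.items())):
        if bone not in poses:
            raise ConfigurationError(f"no poses supplied for bone '{bone}'")
        per_bone = {}
        for pi, posture in enumerate(POSTURES):
            if posture not in poses[bone]:
                raise ConfigurationError(f"bone '{bone}' missing posture '{posture}'")
            tf = poses[bone][posture].transform
            pts = cloud.points
            if overlap_fraction < 1.0:
                k = int(round(overlap_fraction * len(pts)))
                rng = np.random.default_rng(np.random.SeedSequence([seed, bi, pi]))
                idx = rng.choice(len(pts), size=k, replace=False)
                pts = pts[idx]
            per_bone[posture] = PointCloud3D(tf.apply(pts), bone=bone, posture=posture)
        out[bone] = per_bone
    return out


def simulate_skeleton(specs: dict | None = None, poses: dict | None = None,
                      overlap_fraction: float | None = None, seed: int = 0) -> tuple:
    """Full synthetic study: base clouds, absolute ground truth, posture clouds.

    Returns ``(posture_clouds, absolute_poses)``.  Defaults reproduce the
    published study conditions: scanned point counts, measured axis-angle
    poses, 0.2 mm noise, 0.8 overlap.
    """
    if specs is None:
        specs = default_specs(seed=seed)
    if poses is None:
        poses = compose_chain(make_table1_poses())
    if overlap_fraction is None:
        overlap_fraction = next(iter(specs.values())).overlap_fraction
    base = {bone: generate_bone_cloud(spec) for bone, spec in specs.items()}
    posed = pose_clouds(base, poses, overlap_fraction=overlap_fraction, seed=seed)
    return posed, poses


def write_manifest(posture_clouds: dict, poses: dict, outdir,
                   fmt: str = "ply") -> Path:
    """Write per-bone per-posture cloud files plus a manifest JSON.

    The manifest records bone → posture → file together with the
    ground-truth transform (unit quaternion wxyz + translation mm).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for bone, per_bone in posture_clouds.items():
        entries[bone] = {}
        for posture, cloud in per_bone.items():
            fname = f"{bone}_{posture}.{fmt}"
            path = outdir / fname
            if fmt == "ply":
                write_ply(cloud, path)
            elif fmt == "csv":
                write_csv(cloud, path)
            else:
                raise ConfigurationError(f"unsupported cloud format '{fmt}'")
            tf = poses[bone][posture].transform
            entries[bone][posture] = {
                "file": fname,
                "quaternion_wxyz": [float(v) for v in tf.quaternion_wxyz()],
                "translation_mm": [float(v) for v in tf.translation],
            }
    manifest = {
        "units": "mm",
        "postures": list(POSTURES),
        "bones": entries,
        "landmarks": {k: list(v) for k, v in DEFAULT_LANDMARKS.items()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
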
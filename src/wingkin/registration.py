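"""Rigid pose recovery by multi-start minimization of mean nearest-neighbor distance.

Each moving bone cloud (half-extension or flexion posture) is registered to
its extended-posture reference cloud.  The objective is the mean over moving
points of the distance to the nearest reference point — the clouds share no
correspondence, so this is the natural fit criterion; its global minimizer
is sought by multi-start local optimization: dispersed initial rotations
(uniform over the rotation group restricted to a maximum angle), centroid-
aligning initial translations with jitter, an iterative-closest-point local
descent per start, and a derivative-free polish of the winning start
directly on the reported objective.

The reported residual is the *unsquared* mean nearest-neighbor distance in
mm; a squared variant is available via ``squared=True`` where a
mean-squared-distance criterion is wanted.  Nearest neighbors are exact
(KD-tree).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cloud import PointCloud3D, read_cloud
from .errors import EmptyInputError, OptimizationFailureError
from .geometry import RigidTransform


def mean_nn_distance(moving: PointCloud3D, reference: PointCloud3D,
                     squared: bool = False) -> float:
    """Mean over moving points of the (exact) nearest reference-point distance.

    Asymmetric in its arguments: the moving cloud is averaged over, the
    reference cloud is searched.  With ``squared=True`` the squared
    distances are averaged instead (mm² rather than mm).
    """
    if len(moving) == 0 or len(reference) == 0:
        raise EmptyInputError("mean_nn_distance requires non-empty clouds")
    d, _ = cKDTree(reference.points).query(moving.points, k=1)
    return float(np.mean(d ** 2 if squared else d))


def transform_points(cloud: PointCloud3D, t: RigidTransform) -> PointCloud3D:
    """Apply ``x -> R x + T`` to every point; count and order preserved."""
    return cloud.with_points(t.apply(cloud.points))


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_pose`.

    ``n_starts`` local optimizations are run; start 0 is always the identity
    rotation (centroid-aligned), the rest draw rotations uniformly within
    ``max_rotation_deg`` of the identity.  The ICP descent stops when the
    residual improves by less than ``ftol`` (mm) or the update step falls
    below ``xtol`` (mm); the best start is then polished derivative-free on
    the reported objective.
    """

    n_starts: int = 24
    seed: int = 0
    max_rotation_deg: float = 90.0
    translation_jitter_mm: float = 2.0
    max_iter: int = 60
    ftol: float = 1e-8
    xtol: float = 1e-6
    squared: bool = False
    polish: bool = True
    polish_maxfev: int = 250


@dataclass(frozen=True)
class FitResult:
    """Outcome of one registration: best transform and its residual."""

    transform: RigidTransform
    residual_mm: float
    n_starts: int
    converged_starts: int

    def rotation_angle_deg(self) -> float:
        return self.transform.rotation_angle_deg()


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src onto dst (known pairing)."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, dc - rot @ sc)


def _icp(moving_pts: np.ndarray, tree: cKDTree, ref_pts: np.ndarray,
         start: RigidTransform, opts: FitOptions):
    """Iterative closest point from one start; returns (transform, converged)."""
    current = start
    prev_resid = np.inf
    for _ in range(opts.max_iter):
        mapped = current.apply(moving_pts)
        d, idx = tree.query(mapped, k=1)
        resid = float(np.mean(d))
        if prev_resid - resid < opts.ftol and resid <= prev_resid:
            return current, True
        prev_resid = min(prev_resid, resid)
        step = _kabsch(mapped, ref_pts[idx])
        if (np.linalg.norm(step.translation) < opts.xtol
                and step.rotation_angle_deg() < np.rad2deg(opts.xtol)):
            return step @ current, True
        current = step @ current
    return current, False


def _objective_factory(moving_pts, tree, opts):
    def f(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        mapped = moving_pts @ rot.T + x[3:]
        d, _ = tree.query(mapped, k=1)
        return float(np.mean(d ** 2 if opts.squared else d))
    return f


def fit_pose(moving: PointCloud3D, reference: PointCloud3D,
             opts: FitOptions | None = None) -> FitResult:
    """Recover the rigid transform taking ``moving`` onto ``reference``.

    ``moving`` is the half-extension/flexion cloud, ``reference`` the
    extension cloud.  Deterministic given ``opts.seed``; among starts whose
    residuals tie within 1e-9 mm the transform with the smallest rotation
    angle wins.  Raises :class:`IllPosedFitError` on rank-deficient input
    and :class:`OptimizationFailureError` (carrying the best iterate) if no
    start converges.
    """
    opts = opts or FitOptions()
    moving.require_well_posed()
    reference.require_well_posed()
    moving_pts = moving.points
    ref_pts = reference.points
    tree = cKDTree(ref_pts)
    rng = np.random.default_rng(opts.seed)
    ref_centroid = ref_pts.mean(axis=0)
    mov_centroid = moving_pts.mean(axis=0)

    candidates = []  # (residual, angle, transform, converged)
    n_converged = 0
    for k in range(max(1, opts.n_starts)):
        if k == 0:
            rot = np.eye(3)
            jitter = np.zeros(3)
        else:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(0.0, opts.max_rotation_deg))
            rot = Rotation.from_rotvec(angle * axis).as_matrix()
            jitter = rng.normal(scale=opts.translation_jitter_mm, size=3)
        start = RigidTransform(rot, ref_centroid - rot @ mov_centroid + jitter)
        tf, converged = _icp(moving_pts, tree, ref_pts, start, opts)
        n_converged += converged
        resid = mean_nn_distance(transform_points(moving, tf), reference,
                                 squared=opts.squared)
        candidates.append((resid, tf.rotation_angle_deg(), tf, converged))

    # best residual; ties within 1e-9 broken by smallest rotation angle
    best_resid = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_resid + 1e-9]
    resid, _, best_tf, _ = min(tied, key=lambda c: c[1])

    if n_converged == 0:
        raise OptimizationFailureError(
            "no registration start converged",
            best=FitResult(best_tf, resid, max(1, opts.n_starts), 0),
        )

    if opts.polish:
        f = _objective_factory(moving_pts, tree, opts)
        x0 = np.concatenate([
            Rotation.from_matrix(best_tf.rotation).as_rotvec(),
            best_tf.translation,
        ])
        res = minimize(f, x0, method="Powell",
                       options={"maxfev": opts.polish_maxfev,
                                "ftol": opts.ftol, "xtol": opts.xtol})
        if res.fun <= resid:
            best_tf = RigidTransform(
                Rotation.from_rotvec(res.x[:3]).as_matrix(), res.x[3:])
            resid = float(res.fun)

    resid = mean_nn_distance(transform_points(moving, best_tf), reference,
                             squared=opts.squared)
    return FitResult(best_tf, resid, max(1, opts.n_starts), n_converged)


def fit_all(posture_clouds: dict, opts: FitOptions | None = None) -> dict:
    """Register every bone's non-extension clouds to its extension cloud.

    ``posture_clouds`` maps bone → posture → cloud.  Returns bone → posture
    → :class:`FitResult`; the extension entry is the identity with its
    self-distance residual.  Per-fit seeds are derived deterministically
    from ``opts.seed``.
    """
    opts = opts or FitOptions()
    results = {}
    for bi, bone in enumerate(sorted(posture_clouds)):
        per_bone = posture_clouds[bone]
        if "extension" not in per_bone:
            raise EmptyInputError(f"bone '{bone}' has no extension reference cloud")
        ref = per_bone["extension"]
        out = {
            "extension": FitResult(
                RigidTransform.identity(),
                mean_nn_distance(ref, ref, squared=opts.squared),
                0, 0,
            )
        }
        for pi, posture in enumerate(("half_extension", "flexion")):
            if posture not in per_bone:
                continue
            sub_opts = replace(opts, seed=(opts.seed * 7919 + bi * 13 + pi) % (2 ** 31))
            out[posture] = fit_pose(per_bone[posture], ref, sub_opts)
        results[bone] = out
    return results


def fits_to_frame(fits: dict) -> pd.DataFrame:
    """Tabulate fits: bone, posture, quaternion wxyz, translation mm, residual mm."""
    rows = []
    for bone, per_bone in fits.items():
        for posture, fr in per_bone.items():
            q = fr.transform.quaternion_wxyz()
            t = fr.transform.translation
            rows.append({
                "bone": bone, "posture": posture,
                "qw": q[0], "qx": q[1], "qy": q[2], "qz": q[3],
                "tx_mm": t[0], "ty_mm": t[1], "tz_mm": t[2],
                "residual_mm": fr.residual_mm, "n_starts": fr.n_starts,
            })
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> dict:
    """Inverse of :func:`fits_to_frame`."""
    fits = {}
    for _, row in df.iterrows():
        tf = RigidTransform.from_quaternion_wxyz(
            [row.qw, row.qx, row.qy, row.qz], [row.tx_mm, row.ty_mm, row.tz_mm])
        fits.setdefault(row.bone, {})[row.posture] = FitResult(
            tf, float(row.residual_mm), int(row.n_starts), int(row.n_starts))
    return fits


def load_manifest_clouds(manifest_path) -> dict:
    """Read the clouds listed in a synthetic-skeleton manifest JSON."""
    import json

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    clouds = {}
    for bone, per_bone in manifest["bones"].items():
        clouds[bone] = {}
        for posture, entry in per_bone.items():
            fpath = manifest_path.parent / entry["file"]
            if not fpath.exists():
                raise FileNotFoundError(
                    f"cloud file for {bone}/{posture} missing: {fpath}")
            clouds[bone][posture] = read_cloud(fpath, bone=bone, posture=posture)
    return clouds
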
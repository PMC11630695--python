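"""One-DOF spatial four-bar wing mechanism: analysis, synthesis, tendon routing.

The bionic wing skeleton couples four links — humerus (ground), ulna,
radius, carpometacarpus — through four joints: a revolute elbow
(humerus-ulna), a spherical humerus-radius joint, a revolute ulna-metacarpus
wrist, and a universal radius-metacarpus joint.  Kutzbach mobility
6·3 − (5 + 3 + 5 + 4) = 1: a single elbow drive folds the whole wing.

Forward kinematics is solved in closed form.  With the elbow drive angle φ
fixed, the ulna pose is known; the wrist angle ψ must place the universal
center on a sphere of radius |C4 − C2| about the spherical center, which is
a single trigonometric equation A·cosψ + B·sinψ + C = 0; the remaining spin
of the radius about its own long axis is fixed by the universal joint's
axis-orthogonality constraint — a second equation of the same form.  Each
equation has two roots (assembly branches); the branch continuous with the
extension configuration is tracked by continuation along the drive sweep.

Joint synthesis minimizes the summed squared deviation between the
mechanism's bone angles and the measured falcon angles over both folded
postures, by multi-start local optimization over the joint centers and the
two revolute axes (universal axes are derived, the spherical joint has
none).  Per posture the drive angle is chosen so the ulna angle matches the
falcon ulna target exactly, concentrating the residual on radius and
metacarpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    BranchJumpError,
    ConfigurationError,
    InvalidRoutingError,
    OptimizationFailureError,
    UnreachableConfigurationError,
)
from .geometry import RigidTransform, perpendicular_unit, unit
from .synthetic import FALCON_MOTION

JOINT_DOF = {"revolute": 1, "universal": 2, "spherical": 3}

#: finite penalty (deg²) for an unreachable posture inside the synthesis
#: objective — keeps the search landscape finite instead of raising.
UNREACHABLE_PENALTY = 1.0e4


@dataclass(frozen=True)
class JointSpec:
    """One typed joint: kind, center (mm) and 0-2 unit axes."""

    kind: str
    center: np.ndarray
    axes: tuple = ()

    def __post_init__(self):
        if self.kind not in JOINT_DOF:
            raise ConfigurationError(f"unknown joint kind '{self.kind}'")
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        axes = tuple(unit(a) for a in self.axes)
        expected = {"revolute": 1, "universal": 2, "spherical": 0}[self.kind]
        if len(axes) != expected:
            raise ConfigurationError(
                f"{self.kind} joint needs {expected} axes, got {len(axes)}")
        if self.kind == "universal" and abs(np.dot(axes[0], axes[1])) > 1e-9:
            raise ConfigurationError("universal joint axes must be orthogonal")
        object.__setattr__(self, "axes", axes)


def _derive_universal_axes(c2, c4, wrist_axis):
    """Universal-joint axis pair from the radius long axis and the wrist axis.

    The first axis is fixed in the radius body frame, perpendicular to the
    radius long axis; the second, fixed in the metacarpus frame, completes
    an orthogonal pair.  Both are expressed in the common extension frame.
    """
    u = unit(np.asarray(c4, float) - np.asarray(c2, float))
    cr = np.cross(u, wrist_axis)
    a_r = unit(cr) if np.linalg.norm(cr) > 1e-9 else perpendicular_unit(u)
    b_m = unit(np.cross(u, a_r))
    return a_r, b_m


@dataclass(frozen=True)
class MechanismGeometry:
    """Joint centers and axes of the R/S/R/U wing four-bar, extension frame (mm).

    ``elbow_center``/``elbow_axis``: revolute humerus-ulna;
    ``shoulder_r_center``: spherical humerus-radius; ``wrist_u_center``/
    ``wrist_axis``: revolute ulna-metacarpus; ``wrist_r_center``: universal
    radius-metacarpus.  All link body frames coincide with the world frame
    at extension, so attachment points double as world coordinates there.
    """

    elbow_center: np.ndarray
    elbow_axis: np.ndarray
    shoulder_r_center: np.ndarray
    wrist_u_center: np.ndarray
    wrist_axis: np.ndarray
    wrist_r_center: np.ndarray

    def __post_init__(self):
        for name in ("elbow_center", "shoulder_r_center", "wrist_u_center",
                     "wrist_r_center"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        object.__setattr__(self, "elbow_axis", unit(self.elbow_axis))
        object.__setattr__(self, "wrist_axis", unit(self.wrist_axis))
        if np.linalg.norm(self.wrist_r_center - self.shoulder_r_center) < 1e-6:
            raise ConfigurationError("radius link has zero length")

    @property
    def universal_axes(self):
        return _derive_universal_axes(self.shoulder_r_center, self.wrist_r_center,
                                      self.wrist_axis)

    @property
    def radius_length(self) -> float:
        return float(np.linalg.norm(self.wrist_r_center - self.shoulder_r_center))

    def joints(self) -> dict:
        a_r, b_m = self.universal_axes
        return {
            "elbow": JointSpec("revolute", self.elbow_center, (self.elbow_axis,)),
            "shoulder_r": JointSpec("spherical", self.shoulder_r_center),
            "wrist_u": JointSpec("revolute", self.wrist_u_center, (self.wrist_axis,)),
            "wrist_r": JointSpec("universal", self.wrist_r_center, (a_r, b_m)),
        }

    def to_dict(self) -> dict:
        a_r, b_m = self.universal_axes
        return {
            "links": ["humerus", "ulna", "radius", "metacarpus"],
            "joints": {
                "elbow": {"kind": "revolute", "links": ["humerus", "ulna"],
                          "center_mm": self.elbow_center.tolist(),
                          "axes": [self.elbow_axis.tolist()]},
                "shoulder_r": {"kind": "spherical", "links": ["humerus", "radius"],
                               "center_mm": self.shoulder_r_center.tolist(), "axes": []},
                "wrist_u": {"kind": "revolute", "links": ["ulna", "metacarpus"],
                            "center_mm": self.wrist_u_center.tolist(),
                            "axes": [self.wrist_axis.tolist()]},
                "wrist_r": {"kind": "universal", "links": ["radius", "metacarpus"],
                            "center_mm": self.wrist_r_center.tolist(),
                            "axes": [a_r.tolist(), b_m.tolist()]},
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MechanismGeometry":
        j = d["joints"]
        return cls(
            elbow_center=j["elbow"]["center_mm"],
            elbow_axis=j["elbow"]["axes"][0],
            shoulder_r_center=j["shoulder_r"]["center_mm"],
            wrist_u_center=j["wrist_u"]["center_mm"],
            wrist_axis=j["wrist_u"]["axes"][0],
            wrist_r_center=j["wrist_r"]["center_mm"],
        )


def default_geometry() -> MechanismGeometry:
    """Initial mechanism laid out on the synthetic skeleton's bone endpoints.

    Elbow at the humerus distal end, wrist at the ulna distal end, radius
    spanning shoulder-side to wrist-side attachments; revolute axes
    initialized at the measured half-extension rotation axes of ulna and
    metacarpus.
    """
    return MechanismGeometry(
        elbow_center=(0.0, 85.0, 0.0),
        elbow_axis=unit(FALCON_MOTION["ulna"]["half_extension"][0]),
        shoulder_r_center=(8.0, 85.0, 0.0),
        wrist_u_center=(0.0, 185.0, 0.0),
        wrist_axis=unit(FALCON_MOTION["metacarpus"]["half_extension"][0]),
        wrist_r_center=(8.0, 185.0, 0.0),
    )


def mobility(geometry_or_kinds) -> int:
    """Kutzbach mobility: 6·(moving links) − Σ joint constraints.

    Accepts a :class:`MechanismGeometry` or an iterable of joint kind
    strings; the link count is fixed at four (three moving).
    """
    if isinstance(geometry_or_kinds, MechanismGeometry):
        kinds = [j.kind for j in geometry_or_kinds.joints().values()]
    else:
        kinds = list(geometry_or_kinds)
    constraints = sum(6 - JOINT_DOF[k] for k in kinds)
    return 6 * 3 - constraints


@dataclass(frozen=True)
class MechanismState:
    """Solved configuration at one drive angle.

    ``joint_angles_deg`` follows the falcon measurement convention: ulna and
    radius rotation relative to the (ground) humerus, metacarpus rotation
    relative to the ulna — i.e. the wrist revolute coordinate.
    """

    drive_angle_deg: float
    wrist_angle_deg: float
    radius_spin_deg: float
    link_poses: dict
    joint_angles_deg: tuple


def _solve_cos_sin(a: float, b: float, c: float, prev: float):
    """Roots of a·cosx + b·sinx + c = 0 (radians); pick the root nearest prev.

    Returns (x, violation): violation 0 if solvable, else the infeasibility
    magnitude |c| − hypot(a, b) with x = best-effort root.
    """
    r = np.hypot(a, b)
    if r < 1e-14:
        return prev, abs(c)
    delta = np.arctan2(b, a)
    ratio = -c / r
    if abs(ratio) > 1.0:
        # best effort: extremum of the LHS nearest the solution
        x = delta if ratio > 0 else delta + np.pi
        return _nearest_angle(x, prev), (abs(c) - r)
    acos = np.arccos(ratio)
    roots = (delta + acos, delta - acos)
    best = min(roots, key=lambda x: abs(_wrap(x - prev)))
    return _nearest_angle(best, prev), 0.0


def _wrap(x: float) -> float:
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def _nearest_angle(x: float, prev: float) -> float:
    return prev + _wrap(x - prev)


def _minimal_rotation(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction v to direction w by the smallest angle."""
    v = unit(v)
    w = unit(w)
    c = np.cross(v, w)
    s = np.linalg.norm(c)
    d = float(np.dot(v, w))
    if s < 1e-14:
        if d > 0:
            return np.eye(3)
        axis = perpendicular_unit(v)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = c / s
    return Rotation.from_rotvec(np.arctan2(s, d) * axis).as_matrix()


def _solve_state(geom: MechanismGeometry, phi_deg: float,
                 psi_prev: float, gamma_prev: float):
    """Closed-form loop closure at drive angle phi (continuation from prev).

    Returns (state, psi, gamma, violation); violation > 0 marks an
    unreachable configuration (state is then a best-effort iterate).
    """
    c1, a1 = geom.elbow_center, geom.elbow_axis
    c2 = geom.shoulder_r_center
    c3, a3 = geom.wrist_u_center, geom.wrist_axis
    c4 = geom.wrist_r_center
    a_r, b_m = geom.universal_axes
    link_len = geom.radius_length

    t_u = RigidTransform.from_axis_angle(a1, phi_deg, center=c1)
    r_u = t_u.rotation

    # wrist angle: universal center must lie on the sphere |x - C2| = L
    q = c4 - c3
    q_par = np.dot(q, a3) * a3
    q_perp = q - q_par
    alpha = t_u.apply(c3 + q_par)
    beta = r_u @ q_perp
    gvec = r_u @ np.cross(a3, q_perp)
    w0 = alpha - c2
    coef_a = 2.0 * np.dot(w0, beta)
    coef_b = 2.0 * np.dot(w0, gvec)
    coef_c = float(np.dot(w0, w0) + np.dot(q_perp, q_perp) - link_len ** 2)
    psi, viol_pos = _solve_cos_sin(coef_a, coef_b, coef_c, psi_prev)

    t_m = t_u @ RigidTransform.from_axis_angle(a3, np.rad2deg(psi), center=c3)
    p4 = t_m.apply(c4)
    w = p4 - c2

    # radius spin about its own long axis from the universal orthogonality
    if np.linalg.norm(w) < 1e-12:
        return None, psi, gamma_prev, max(viol_pos, link_len)
    w_hat = unit(w)
    r0 = _minimal_rotation(c4 - c2, w)
    m = t_m.rotation @ b_m
    u0 = r0 @ a_r
    u_par = np.dot(u0, w_hat) * w_hat
    u_perp = u0 - u_par
    gamma, viol_ori = _solve_cos_sin(
        float(np.dot(u_perp, m)), float(np.dot(np.cross(w_hat, u_perp), m)),
        float(np.dot(u_par, m)), gamma_prev)

    r_r = Rotation.from_rotvec(gamma * w_hat).as_matrix() @ r0
    t_r = RigidTransform(r_r, c2 - r_r @ c2)

    violation = max(viol_pos, 0.0) + max(viol_ori, 0.0)
    ulna_angle = abs(phi_deg)
    radius_angle = t_r.rotation_angle_deg()
    met_rel_angle = abs(np.rad2deg(psi))
    state = MechanismState(
        drive_angle_deg=phi_deg,
        wrist_angle_deg=float(np.rad2deg(psi)),
        radius_spin_deg=float(np.rad2deg(gamma)),
        link_poses={"humerus": RigidTransform.identity(), "ulna": t_u,
                    "radius": t_r, "metacarpus": t_m},
        joint_angles_deg=(ulna_angle, radius_angle, met_rel_angle),
    )
    return state, psi, gamma, violation


def sweep(geometry: MechanismGeometry, drive_angles_deg,
          branch_tol_deg: float = 5.0, raise_on_unreachable: bool = True):
    """Solve the loop at each drive angle, tracking the extension branch.

    ``drive_angles_deg`` must start at (or near) 0; continuation carries the
    branch from step to step.  A step-to-step jump in the wrist angle or
    radius spin larger than ``branch_tol_deg`` raises
    :class:`BranchJumpError`; an unsolvable loop raises
    :class:`UnreachableConfigurationError` (or, with
    ``raise_on_unreachable=False``, returns the violation so callers can
    penalize it).

    Returns (states, violations) lists aligned with the input angles.
    """
    psi, gamma = 0.0, 0.0
    states, violations = [], []
    for phi in drive_angles_deg:
        state, new_psi, new_gamma, viol = _solve_state(geometry, float(phi), psi, gamma)
        if viol > 1e-8:
            if raise_on_unreachable:
                raise UnreachableConfigurationError(
                    f"loop cannot close at drive angle {phi:.2f} deg "
                    f"(violation {viol:.3g})")
            states.append(state)
            violations.append(viol)
            continue
        jump = max(abs(np.rad2deg(new_psi - psi)), abs(np.rad2deg(new_gamma - gamma)))
        if states and jump > branch_tol_deg + abs(phi - states[-1].drive_angle_deg) * 2.0:
            raise BranchJumpError(
                f"assembly branch jump of {jump:.1f} deg at drive {phi:.2f} deg")
        psi, gamma = new_psi, new_gamma
        states.append(state)
        violations.append(0.0)
    return states, violations


def _drive_grid(target_deg: float, step_deg: float):
    n = max(2, int(np.ceil(abs(target_deg) / step_deg)) + 1)
    return np.linspace(0.0, target_deg, n)


def forward_kinematics(geometry: MechanismGeometry, drive_angle_deg: float,
                       step_deg: float = 2.0) -> MechanismState:
    """State at one drive angle, on the branch continuous with extension.

    Internally sweeps from 0 to the requested angle in ``step_deg``
    increments so the correct assembly branch is followed.
    """
    states, _ = sweep(geometry, _drive_grid(drive_angle_deg, step_deg))
    return states[-1]


def loop_closure_residual(geometry: MechanismGeometry, state: MechanismState) -> float:
    """Max violation of the closure constraints at a state (mm / dimensionless).

    Checks the spherical center, the universal center coincidence, and the
    universal axis orthogonality; the two revolute joints are exact by
    construction.
    """
    t_r = state.link_poses["radius"]
    t_m = state.link_poses["metacarpus"]
    a_r, b_m = geometry.universal_axes
    sph = np.linalg.norm(t_r.apply(geometry.shoulder_r_center)
                         - geometry.shoulder_r_center)
    uni = np.linalg.norm(t_r.apply(geometry.wrist_r_center)
                         - t_m.apply(geometry.wrist_r_center))
    ortho = abs(np.dot(t_r.rotation @ a_r, t_m.rotation @ b_m))
    return float(max(sph, uni, ortho))


def falcon_targets(source: str = "table1") -> dict:
    """Falcon bone-angle targets per posture (deg).

    ``source='table1'`` uses the measured skeleton kinematics (default).
    ``source='table2'`` uses the falcon column of the mechanism-comparison
    table, whose radius entries (15.72, 37.58) differ from the measured
    radius row — the two readings are kept selectable rather than silently
    reconciled.
    """
    t = {
        "half_extension": {
            "ulna": FALCON_MOTION["ulna"]["half_extension"][1],
            "radius": FALCON_MOTION["radius"]["half_extension"][1],
            "metacarpus": FALCON_MOTION["metacarpus"]["half_extension"][1],
        },
        "flexion": {
            "ulna": FALCON_MOTION["ulna"]["flexion"][1],
            "radius": FALCON_MOTION["radius"]["flexion"][1],
            "metacarpus": FALCON_MOTION["metacarpus"]["flexion"][1],
        },
    }
    if source == "table2":
        t["half_extension"]["radius"] = 15.72
        t["flexion"]["radius"] = 37.58
    elif source != "table1":
        raise ConfigurationError(f"unknown target source '{source}'")
    return t


_POSTURE_ORDER = ("half_extension", "flexion")
_TARGET_BONES = ("ulna", "radius", "metacarpus")


def _posture_states(geometry: MechanismGeometry, targets: dict,
                    step_deg: float = 2.5, drive_sign: float = 1.0):
    """Mechanism states at the two postures, driving the ulna to its target.

    The drive angle per posture is ±(ulna target): the elbow revolute
    coordinate equals the ulna rotation angle, so the ulna deviation is zero
    by construction wherever the loop closes.  Returns
    {posture: (state | None, violation)}.
    """
    phis = {p: drive_sign * targets[p]["ulna"] for p in _POSTURE_ORDER}
    phi_max = max(phis.values(), key=abs)
    grid = list(_drive_grid(phi_max, step_deg))
    for p in phis.values():  # make sure both posture angles are grid points
        if not any(np.isclose(p, g, atol=1e-12) for g in grid):
            grid.append(p)
    grid = sorted(set(np.round(grid, 12)), key=abs)
    try:
        states, viols = sweep(geometry, grid, raise_on_unreachable=False)
    except BranchJumpError:
        return {p: (None, UNREACHABLE_PENALTY ** 0.5) for p in _POSTURE_ORDER}
    out = {}
    for posture, phi in phis.items():
        idx = int(np.argmin([abs(g - phi) for g in grid]))
        out[posture] = (states[idx], viols[idx])
    return out


def fit_residual(geometry: MechanismGeometry, targets: dict | None = None,
                 return_table: bool = False):
    """Summed squared bone-angle deviation (deg²) of the mechanism vs falcon.

    Over both folded postures and the three measured bones; the ulna term is
    zero by the matched-drive convention.  An unreachable posture
    contributes a finite penalty (1e4 deg² plus the squared constraint
    violation) so synthesis can continue through infeasible geometry.
    """
    targets = targets or falcon_targets()
    posture_states = _posture_states(geometry, targets)
    resid = 0.0
    rows = []
    for posture in _POSTURE_ORDER:
        state, viol = posture_states[posture]
        if state is None or viol > 1e-8:
            resid += UNREACHABLE_PENALTY + viol ** 2
            for bone in _TARGET_BONES:
                rows.append({"posture": posture, "bone": bone,
                             "falcon_deg": targets[posture][bone],
                             "mechanical_deg": np.nan, "deviation_deg": np.nan})
            continue
        mech = dict(zip(_TARGET_BONES, state.joint_angles_deg))
        for bone in _TARGET_BONES:
            dev = mech[bone] - targets[posture][bone]
            resid += dev ** 2
            rows.append({"posture": posture, "bone": bone,
                         "falcon_deg": targets[posture][bone],
                         "mechanical_deg": mech[bone], "deviation_deg": dev})
    if return_table:
        return float(resid), pd.DataFrame(rows)
    return float(resid)


# ---------------------------------------------------------------------------
# joint-placement synthesis

@dataclass(frozen=True)
class SynthesisOptions:
    """Multi-start options for :func:`optimize_joints`.

    Joint centers move inside a box of half-width ``center_box_mm`` around
    their initial positions; revolute axes are free directions, started
    within ``axis_cone_deg`` of the initial axes.  Remaining starts are
    skipped once the best residual falls below ``stop_residual`` (deg²):
    the mechanism then reproduces the targets to numerical precision and no
    later start can improve a best-of-N.
    """

    n_starts: int = 32
    seed: int = 0
    center_box_mm: float = 25.0
    axis_cone_deg: float = 30.0
    max_nfev: int = 300
    target_source: str = "table1"
    stop_residual: float = 1e-10


def _axis_to_angles(a):
    a = unit(a)
    return np.array([np.arccos(np.clip(a[2], -1, 1)), np.arctan2(a[1], a[0])])


def _angles_to_axis(polar, azim):
    s = np.sin(polar)
    return np.array([s * np.cos(azim), s * np.sin(azim), np.cos(polar)])


def _pack(geom: MechanismGeometry) -> np.ndarray:
    return np.concatenate([
        geom.elbow_center, geom.shoulder_r_center, geom.wrist_u_center,
        geom.wrist_r_center, _axis_to_angles(geom.elbow_axis),
        _axis_to_angles(geom.wrist_axis),
    ])


def _unpack(x: np.ndarray) -> MechanismGeometry:
    return MechanismGeometry(
        elbow_center=x[0:3], shoulder_r_center=x[3:6],
        wrist_u_center=x[6:9], wrist_r_center=x[9:12],
        elbow_axis=_angles_to_axis(x[12], x[13]),
        wrist_axis=_angles_to_axis(x[14], x[15]),
    )


def _deviation_vector(x: np.ndarray, targets: dict) -> np.ndarray:
    """Six per-bone angle deviations (deg) for least-squares synthesis.

    Unreachable postures map to large smooth entries growing with the
    constraint violation, steering the optimizer back to feasibility.
    """
    try:
        geom = _unpack(x)
    except ConfigurationError:
        return np.full(6, 100.0)
    posture_states = _posture_states(geom, targets)
    dev = []
    for posture in _POSTURE_ORDER:
        state, viol = posture_states[posture]
        if state is None or viol > 1e-8:
            dev.extend([100.0 + 10.0 * viol] * 3)
            continue
        mech = dict(zip(_TARGET_BONES, state.joint_angles_deg))
        dev.extend(mech[b] - targets[posture][b] for b in _TARGET_BONES)
    return np.asarray(dev)


def optimize_joints(initial: MechanismGeometry, targets: dict | None = None,
                    opts: SynthesisOptions | None = None):
    """Multi-start synthesis of joint centers and revolute axes.

    Minimizes :func:`fit_residual` over the 16 free parameters (four
    centers, two axis directions); deterministic given ``opts.seed``.
    Returns ``(best_geometry, comparison_table)`` where the table lists
    falcon vs mechanical angles and signed deviations per bone and posture.
    """
    opts = opts or SynthesisOptions()
    targets = targets or falcon_targets(opts.target_source)
    rng = np.random.default_rng(opts.seed)
    x_init = _pack(initial)
    lower = x_init.copy()
    upper = x_init.copy()
    lower[:12] -= opts.center_box_mm
    upper[:12] += opts.center_box_mm
    lower[12:] = -np.inf
    upper[12:] = np.inf

    best = None
    n_ok = 0
    for k in range(max(1, opts.n_starts)):
        x0 = x_init.copy()
        if k > 0:
            x0[:12] = rng.uniform(lower[:12], upper[:12])
            x0[12:] += rng.normal(scale=np.deg2rad(opts.axis_cone_deg / 2.0), size=4)
        try:
            sol = least_squares(
                _deviation_vector, x0, args=(targets,), method="trf",
                bounds=(lower, upper), max_nfev=opts.max_nfev,
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except (UnreachableConfigurationError, BranchJumpError):
            continue
        resid = fit_residual(_unpack(sol.x), targets)
        if resid < UNREACHABLE_PENALTY:
            n_ok += 1
        if best is None or resid < best[0]:
            best = (resid, sol.x)
        if best[0] <= opts.stop_residual:
            break
    if best is None or n_ok == 0:
        raise OptimizationFailureError(
            "all synthesis starts were infeasible",
            best=None if best is None else _unpack(best[1]))
    geometry = _unpack(best[1])
    _, table = fit_residual(geometry, targets, return_table=True)
    return geometry, table


# ---------------------------------------------------------------------------
# tendon routing

@dataclass(frozen=True)
class TendonRouting:
    """A straight-line tendon between anchors on two different links."""

    name: str
    proximal_link: str
    proximal_anchor: np.ndarray
    distal_link: str
    distal_anchor: np.ndarray

    def __post_init__(self):
        links = {"humerus", "ulna", "radius", "metacarpus"}
        if self.proximal_link not in links or self.distal_link not in links:
            raise InvalidRoutingError("anchors must attach to mechanism links")
        if self.proximal_link == self.distal_link:
            raise InvalidRoutingError(
                f"routing '{self.name}' attaches both anchors to "
                f"'{self.proximal_link}'")
        object.__setattr__(self, "proximal_anchor",
                           np.asarray(self.proximal_anchor, float).reshape(3))
        object.__setattr__(self, "distal_anchor",
                           np.asarray(self.distal_anchor, float).reshape(3))


def default_routings(geometry: MechanismGeometry | None = None) -> list:
    """The 3 × 3 + 3 × 3 candidate anchor grids for the two tendon analogs.

    Three proximal anchors (I-III) on the humerus and three distal (i-iii)
    on the ulna for the biceps analog on the anterior side of the elbow;
    the mirrored grids (A-C, a-c) on the posterior side for the triceps
    analog.  Anchor posts stand off perpendicular to the elbow axis so the
    tendon crosses the joint with a useful moment arm regardless of how the
    synthesized axis is oriented.
    """
    geometry = geometry or default_geometry()
    c1 = geometry.elbow_center
    axis = geometry.elbow_axis
    along = unit(geometry.wrist_u_center - c1)  # ulna long direction
    # anchor stand-off: perpendicular to the elbow axis, as anterior as possible
    lateral = np.array([1.0, 0.0, 0.0]) - np.dot([1.0, 0.0, 0.0], axis) * axis
    if np.linalg.norm(lateral) < 0.3:
        lateral = np.cross(axis, along)
    lateral = unit(lateral)
    routings = []
    offsets = {"I": 16.0, "II": 26.0, "III": 36.0}
    spans = {"i": 18.0, "ii": 28.0, "iii": 38.0}
    for pl, off in offsets.items():
        for dl, span in spans.items():
            routings.append(TendonRouting(
                name=f"biceps:{pl}-{dl}",
                proximal_link="humerus",
                proximal_anchor=c1 + off * lateral - 10.0 * along,
                distal_link="ulna",
                distal_anchor=c1 + 0.5 * off * lateral + span * along,
            ))
    for pl, off in zip(("A", "B", "C"), offsets.values()):
        for dl, span in zip(("a", "b", "c"), spans.values()):
            routings.append(TendonRouting(
                name=f"triceps:{pl}-{dl}",
                proximal_link="humerus",
                proximal_anchor=c1 - off * lateral - 10.0 * along,
                distal_link="ulna",
                distal_anchor=c1 - 0.5 * off * lateral + span * along,
            ))
    return routings


def tendon_excursion(geometry: MechanismGeometry, routing: TendonRouting,
                     drive_angles_deg) -> pd.DataFrame:
    """Straight anchor-to-anchor tendon length over a drive sweep.

    The excursion column is length minus the length at the first (extension)
    sweep point; the biceps and triceps analogs change length in opposite
    directions during a fold (antagonist pair).
    """
    drive_angles_deg = np.atleast_1d(np.asarray(drive_angles_deg, float))
    states, _ = sweep(geometry, drive_angles_deg)
    lengths = []
    for state in states:
        p = state.link_poses[routing.proximal_link].apply(routing.proximal_anchor)
        d = state.link_poses[routing.distal_link].apply(routing.distal_anchor)
        lengths.append(float(np.linalg.norm(p - d)))
    lengths = np.asarray(lengths)
    return pd.DataFrame({
        "routing": routing.name,
        "drive_angle_deg": drive_angles_deg,
        "length_mm": lengths,
        "excursion_mm": lengths - lengths[0],
    })


def check_actuation_limits(excursions: dict | pd.DataFrame,
                           band_mm=(10.0, 20.0)) -> pd.DataFrame:
    """Flag routings whose fully-folded |excursion| lies inside the band.

    ``excursions`` maps routing name → excursion table (or is their concat);
    the fully folded value is the one at the last sweep point, where the
    largest displacement occurs.  Screening against an actuator force limit
    needs a force model, which is out of scope here; only the displacement
    band (default 10-20 mm) is applied.
    """
    if isinstance(excursions, dict):
        frames = list(excursions.values())
    else:
        frames = [g for _, g in excursions.groupby("routing", sort=True)]
    rows = []
    for df in frames:
        final = float(df["excursion_mm"].iloc[-1])
        rows.append({
            "routing": str(df["routing"].iloc[0]),
            "excursion_mm": final,
            "abs_excursion_mm": abs(final),
            "within_band": bool(band_mm[0] <= abs(final) <= band_mm[1]),
        })
    return pd.DataFrame(rows).sort_values("routing").reset_index(drop=True)
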
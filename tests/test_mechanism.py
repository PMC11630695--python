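"""Spatial four-bar mechanism: mobility, closure, synthesis, tendon routing."""

import numpy as np
import pandas as pd
import pytest

from wingkin.errors import InvalidRoutingError
from wingkin.mechanism import (
    SynthesisOptions,
    TendonRouting,
    check_actuation_limits,
    default_geometry,
    default_routings,
    falcon_targets,
    fit_residual,
    forward_kinematics,
    loop_closure_residual,
    mobility,
    optimize_joints,
    sweep,
    tendon_excursion,
)


class TestMobility:
    def test_canonical_rsru_has_one_dof(self):
        assert mobility(default_geometry()) == 1

    def test_all_spherical_is_six(self):
        assert mobility(["spherical"] * 4) == 6

    def test_all_revolute_is_overconstrained(self):
        assert mobility(["revolute"] * 4) == -2

    def test_dropping_universal_constraint_raises_mobility(self):
        assert mobility(["revolute", "spherical", "revolute", "spherical"]) == 2


class TestForwardKinematics:
    def test_zero_drive_is_extension_reference(self):
        state = forward_kinematics(default_geometry(), 0.0)
        assert state.joint_angles_deg == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)
        for pose in state.link_poses.values():
            assert pose.rotation_angle_deg() == pytest.approx(0.0, abs=1e-9)

    def test_loop_closure_over_fold_sweep(self):
        """Residual < 1e-8 at every accepted state of a 60-step fold."""
        geom = default_geometry()
        states, _ = sweep(geom, np.linspace(0.0, 60.0, 61))
        worst = max(loop_closure_residual(geom, s) for s in states)
        assert worst < 1e-8

    def test_small_step_continuity(self):
        """Metacarpal angle changes O(delta) under a small drive step."""
        geom = default_geometry()
        base = forward_kinematics(geom, 20.0)
        for delta in (0.1, 0.01):
            stepped = forward_kinematics(geom, 20.0 + delta)
            change = abs(stepped.joint_angles_deg[2] - base.joint_angles_deg[2])
            assert change < 5.0 * delta + 1e-9

    def test_ulna_and_metacarpal_fold_together(self):
        """Elbow-wrist coupling: both angles grow monotonically over the fold."""
        states, _ = sweep(default_geometry(), np.linspace(0.0, 40.0, 41))
        ulna = [s.joint_angles_deg[0] for s in states]
        met = [s.joint_angles_deg[2] for s in states]
        assert all(np.diff(ulna) > -1e-9)
        assert all(np.diff(met) > -1e-9)


class TestFitResidual:
    def test_zero_when_targets_equal_mechanism(self):
        geom = default_geometry()
        _, table = fit_residual(geom, return_table=True)
        targets = {
            p: dict(zip(g.bone, g.mechanical_deg))
            for p, g in table.groupby("posture")}
        assert fit_residual(geom, targets) == pytest.approx(0.0, abs=1e-18)

    def test_single_two_degree_error_gives_four(self):
        geom = default_geometry()
        _, table = fit_residual(geom, return_table=True)
        targets = {p: dict(zip(g.bone, g.mechanical_deg))
                   for p, g in table.groupby("posture")}
        targets["flexion"]["radius"] += 2.0
        assert fit_residual(geom, targets) == pytest.approx(4.0, abs=1e-9)

    def test_table_matches_independent_forward_kinematics(self):
        """Re-evaluating FK at the fitted drive angles reproduces the table."""
        geom = default_geometry()
        targets = falcon_targets()
        _, table = fit_residual(geom, targets, return_table=True)
        for posture, drive in (("half_extension", 16.42), ("flexion", 38.83)):
            state = forward_kinematics(geom, drive, step_deg=0.5)
            mech = dict(zip(("ulna", "radius", "metacarpus"),
                            state.joint_angles_deg))
            sub = table[table.posture == posture].set_index("bone")
            for bone in mech:
                assert sub.loc[bone, "mechanical_deg"] == pytest.approx(
                    mech[bone], abs=1e-9)


class TestOptimizeJoints:
    def test_recovers_targets_from_known_mechanism(self):
        """Inverse crime: targets generated by a feasible mechanism are met."""
        geom = default_geometry()
        _, table = fit_residual(geom, return_table=True)
        targets = {p: dict(zip(g.bone, g.mechanical_deg))
                   for p, g in table.groupby("posture")}
        fitted, _ = optimize_joints(geom, targets,
                                    SynthesisOptions(n_starts=6, seed=2))
        assert fit_residual(fitted, targets) < 1e-4

    def test_deterministic_given_seed(self):
        opts = SynthesisOptions(n_starts=3, seed=5)
        g1, t1 = optimize_joints(default_geometry(), opts=opts)
        g2, t2 = optimize_joints(default_geometry(), opts=opts)
        assert np.allclose(g1.elbow_center, g2.elbow_center)
        pd.testing.assert_frame_equal(t1, t2)

    def test_comparison_table_shape(self):
        _, table = optimize_joints(default_geometry(),
                                   opts=SynthesisOptions(n_starts=2, seed=1))
        assert set(table.columns) == {
            "posture", "bone", "falcon_deg", "mechanical_deg", "deviation_deg"}
        assert len(table) == 6
        # ulna deviation is zero by the matched-drive convention
        assert table[table.bone == "ulna"].deviation_deg.abs().max() < 1e-12


class TestTendons:
    def test_zero_sweep_zero_excursion(self):
        geom = default_geometry()
        routing = default_routings(geom)[0]
        df = tendon_excursion(geom, routing, [0.0])
        assert df.excursion_mm.iloc[0] == 0.0

    def test_antagonist_pair_changes_length_oppositely(self):
        geom = default_geometry()
        angles = np.linspace(0.0, 38.83, 20)
        routings = {r.name: r for r in default_routings(geom)}
        bic = tendon_excursion(geom, routings["biceps:II-ii"], angles)
        tri = tendon_excursion(geom, routings["triceps:B-b"], angles)
        assert bic.excursion_mm.iloc[-1] * tri.excursion_mm.iloc[-1] < 0

    def test_excursion_monotone_along_fold(self):
        geom = default_geometry()
        routing = default_routings(geom)[4]  # biceps II-ii
        df = tendon_excursion(geom, routing, np.linspace(0.0, 38.83, 40))
        diffs = np.diff(df.length_mm.to_numpy())
        assert (diffs > -1e-9).all() or (diffs < 1e-9).all()

    def test_max_excursion_at_fully_folded_end(self):
        geom = default_geometry()
        for routing in default_routings(geom):
            df = tendon_excursion(geom, routing, np.linspace(0.0, 38.83, 40))
            assert df.excursion_mm.abs().idxmax() == len(df) - 1

    def test_same_link_routing_rejected(self):
        with pytest.raises(InvalidRoutingError):
            TendonRouting("bad", "ulna", [0, 0, 0], "ulna", [1, 0, 0])

    def test_band_screening(self):
        mk = lambda name, exc: pd.DataFrame(
            {"routing": [name] * 2, "drive_angle_deg": [0.0, 30.0],
             "length_mm": [50.0, 50.0 + exc], "excursion_mm": [0.0, exc]})
        report = check_actuation_limits({"a": mk("a", 15.0), "b": mk("b", 25.0),
                                         "c": mk("c", -12.0)})
        flags = report.set_index("routing").within_band
        assert bool(flags["a"]) and bool(flags["c"]) and not bool(flags["b"])

    def test_nine_biceps_routing_combinations(self):
        names = [r.name for r in default_routings() if r.name.startswith("biceps")]
        assert len(names) == 9
        assert len(set(names)) == 9
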
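"""Mobility, closed-form IK/FK, calibration, constraints, trajectories."""

import numpy as np
import pytest

from rehabgait.errors import (
    CalibrationError,
    CapabilityError,
    ConfigError,
    InfeasiblePoseError,
    SingularGeometryError,
)
from rehabgait.kinematics import (
    ActuatorLengths,
    CalibrationRow,
    MechanismGeometry,
    MechanismTopology,
    Pose,
    TrajectorySample,
    branch_points,
    calibrate_lumped_offsets,
    constraint_residuals,
    forward_kinematics,
    inverse_kinematics,
    mobility,
    passive_displacements,
    trajectory_commands,
)
from rehabgait.synthetic import gen_calibration_rows, gen_trajectory

# Full link dimensions consistent with the verification-row offsets:
# m = L/2 - a - c = 340, q = b + c = 440.
FULL = MechanismGeometry.full(a=100.0, b=300.0, c=140.0, L=1160.0)
LUMPED = MechanismGeometry.lumped(340.0, 440.0)


class TestMobility:
    @pytest.mark.parametrize("counts,dof", [
        ((11, 12, 12, 3), 3),    # the actuator itself
        ((1, 0, 0, 0), 0),       # a single fixed body
        ((14, 18, 36, 0), 6),
    ])
    def test_gruebler_kutzbach(self, counts, dof):
        assert mobility(MechanismTopology(*counts)) == dof

    def test_result_is_exact_int(self):
        assert isinstance(mobility(MechanismTopology()), int)

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            mobility(MechanismTopology(-1, 12, 12, 3))


class TestPassiveDisplacements:
    @pytest.mark.parametrize("pose,expected", [
        ((300, 400, -1000), (400, 400, 300)),
        ((0, 0, 0), (0, 0, 0)),
        ((-400, 450, -950), (450, 450, -400)),
    ])
    def test_coupling(self, pose, expected):
        d = passive_displacements(Pose(*pose))
        assert (d.d1, d.d2, d.d3) == expected

    def test_d1_equals_d2_structurally(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = Pose(*rng.uniform(-500, 500, size=3))
            d = passive_displacements(p)
            assert d.d1 == d.d2 == p.py
            assert d.d3 == p.px


class TestInverseKinematics:
    def test_px_symmetry(self):
        lengths = inverse_kinematics(LUMPED, Pose(0.0, 123.0, -800.0))
        assert lengths.L1 == lengths.L2

    def test_matches_geometric_branch_point_distances(self):
        """Closed form vs the independent point construction: |CiBi| from
        vector addition must equal the formula lengths."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            pose = Pose(float(rng.uniform(-500, 500)),
                        float(rng.uniform(0, 440)),
                        float(rng.uniform(-1500, -500)))
            pts = branch_points(FULL, pose)
            dist = [float(np.linalg.norm(b - c))
                    for c, b in zip(pts.C, pts.B)]
            lengths = inverse_kinematics(FULL, pose)
            assert np.allclose(dist, lengths.as_array(), atol=1e-9)

    def test_py_translation_invariance_branches_1_2(self):
        a = inverse_kinematics(LUMPED, Pose(120.0, 100.0, -900.0))
        b = inverse_kinematics(LUMPED, Pose(120.0, 400.0, -900.0))
        assert a.L1 == b.L1 and a.L2 == b.L2

    def test_px_translation_invariance_branch_3(self):
        a = inverse_kinematics(LUMPED, Pose(-200.0, 100.0, -900.0))
        b = inverse_kinematics(LUMPED, Pose(350.0, 100.0, -900.0))
        assert a.L3 == b.L3

    def test_degenerate_zero_length_pose_rejected(self):
        with pytest.raises(InfeasiblePoseError, match="degenerate"):
            inverse_kinematics(LUMPED, Pose(-340.0, 100.0, 0.0))


class TestVerificationRows:
    def test_printed_lengths_reproduced(self, table7_rows):
        """With offsets calibrated from the rows themselves, every printed
        length must be reproduced within the 0.5 mm print tolerance —
        except the row-1 branch-3 cell, which is flagged as an outlier."""
        result = calibrate_lumped_offsets(table7_rows)
        geom = result.geometry
        assert geom.m == pytest.approx(340.0, abs=0.5)
        assert geom.q == pytest.approx(440.0, abs=0.5)
        assert result.reports["q"].outliers == [(0, 3)]
        printed = [(r.L1, r.L2, r.L3) for r in table7_rows]
        for i, row in enumerate(table7_rows):
            lengths = inverse_kinematics(geom, row.pose).as_array()
            for b in range(3):
                if (i, b + 1) in result.reports["q"].outliers:
                    continue
                assert lengths[b] == pytest.approx(printed[i][b], abs=0.5)

    def test_forward_kinematics_inverts_printed_row(self, table7_rows):
        result = calibrate_lumped_offsets(table7_rows)
        row = table7_rows[1]          # (200, 350, -900)
        pose = forward_kinematics(result.geometry,
                                  ActuatorLengths(row.L1, row.L2, row.L3))
        assert pose.px == pytest.approx(200, abs=0.5)
        assert pose.py == pytest.approx(350, abs=0.5)
        assert pose.pz == pytest.approx(-900, abs=0.5)


class TestForwardKinematics:
    def test_round_trip_on_sampled_workspace(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            pose = Pose(float(rng.uniform(-500, 500)),
                        float(rng.uniform(0, 440)),
                        float(rng.uniform(-1500, -500)))
            lengths = inverse_kinematics(LUMPED, pose)
            back = forward_kinematics(LUMPED, lengths)
            err = max(abs(back.px - pose.px), abs(back.py - pose.py),
                      abs(back.pz - pose.pz))
            worst = max(worst, err)
        assert worst < 1e-9

    def test_equal_lengths_give_px_zero(self):
        pose = forward_kinematics(LUMPED,
                                  ActuatorLengths(900.0, 900.0, 850.0))
        assert pose.px == 0.0

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(InfeasiblePoseError, match="inconsistent"):
            forward_kinematics(LUMPED, ActuatorLengths(2000.0, 300.0, 900.0))

    def test_zero_m_singular(self):
        geom = MechanismGeometry(m=0.0, q=440.0, mode="lumped")
        with pytest.raises(SingularGeometryError):
            forward_kinematics(geom, ActuatorLengths(900.0, 900.0, 850.0))

    def test_py_root_selected_by_workspace_box(self):
        # Py = 485 and its mirror 395 about q = 440 give identical lengths;
        # the box decides which root FK returns.
        lengths = inverse_kinematics(LUMPED, Pose(0.0, 485.0, -900.0))
        mirror = forward_kinematics(LUMPED, lengths)   # default box [0, q]
        assert mirror.py == pytest.approx(395.0, abs=1e-9)
        pose = forward_kinematics(LUMPED, lengths, py_box=(440.0, 600.0))
        assert pose.py == pytest.approx(485.0, abs=1e-9)
        with pytest.raises(InfeasiblePoseError, match="workspace"):
            forward_kinematics(LUMPED, lengths, py_box=(100.0, 300.0))


class TestConstraintResiduals:
    def test_zero_by_construction(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pose = Pose(float(rng.uniform(-500, 500)),
                        float(rng.uniform(0, 440)),
                        float(rng.uniform(-1500, -500)))
            res = constraint_residuals(FULL, pose)
            assert max(abs(r) for r in res) < 1e-9

    def test_perturbed_length_first_order(self):
        pose = Pose(200.0, 350.0, -900.0)
        lengths = inverse_kinematics(FULL, pose)
        bumped = ActuatorLengths(lengths.L1 + 1.0, lengths.L2, lengths.L3)
        res = constraint_residuals(FULL, pose, bumped)
        # (L1 + 1)^2 - L1^2 = 2 L1 + 1
        assert res[0] == pytest.approx(2.0 * lengths.L1 + 1.0, rel=1e-12)
        assert abs(res[1]) < 1e-9 and abs(res[2]) < 1e-9

    def test_degenerate_coincidence_still_zero(self):
        # Px = 0 puts C3 on M3; the constraint must still hold.
        res = constraint_residuals(FULL, Pose(0.0, 350.0, -900.0))
        assert max(abs(r) for r in res) < 1e-9
        # C1/C2 on M1/M2 when Py = c.
        res = constraint_residuals(FULL, Pose(150.0, FULL.c, -900.0))
        assert max(abs(r) for r in res) < 1e-9

    def test_lumped_geometry_lacks_capability(self):
        with pytest.raises(CapabilityError):
            constraint_residuals(LUMPED, Pose(0.0, 100.0, -900.0))


class TestCalibration:
    def test_row1_gives_m_340_unambiguously(self, table7_rows):
        result = calibrate_lumped_offsets([table7_rows[0]],
                                          use_branches=(1, 2))
        rep = result.reports["m"]
        assert result.geometry.m == pytest.approx(340.0, abs=0.5)
        assert not rep.ambiguous
        assert rep.outliers == []

    def test_noise_free_synthetic_rows_recover_exactly(self):
        true = MechanismGeometry.lumped(123.4, 567.8)
        rng = np.random.default_rng(1)
        poses = [Pose(float(rng.uniform(-400, 400)),
                      float(rng.uniform(0, 560)),
                      float(rng.uniform(-1500, -500))) for _ in range(10)]
        rows = gen_calibration_rows(true, poses, noise_sd_mm=0.0)
        result = calibrate_lumped_offsets(rows)
        assert result.geometry.m == pytest.approx(123.4, abs=1e-9)
        assert result.geometry.q == pytest.approx(567.8, abs=1e-9)

    def test_noisy_recovery_within_tolerance(self):
        """50 rows with 0.1 mm Gaussian length noise must recover the
        lumped offsets within 0.05 mm."""
        true = MechanismGeometry.lumped(340.0, 440.0)
        rng = np.random.default_rng(2)
        poses = [Pose(float(rng.uniform(-400, 400)),
                      float(rng.uniform(0, 430)),
                      float(rng.uniform(-1500, -500))) for _ in range(50)]
        rows = gen_calibration_rows(true, poses, noise_sd_mm=0.1, seed=12)
        result = calibrate_lumped_offsets(rows)
        assert abs(result.geometry.m - 340.0) < 0.05
        # q is informed by 50 branch-3 cells only (half the data of m) and
        # with lower geometric sensitivity; bound it at 3x its standard
        # error (~0.06 mm) rather than m's tighter band.
        assert abs(result.geometry.q - 440.0) < 0.18

    def test_single_branch3_row_flags_two_root_ambiguity(self, table7_rows):
        result = calibrate_lumped_offsets([table7_rows[1]],
                                          use_branches=(3,))
        assert result.reports["q"].ambiguous
        assert len(result.reports["q"].solutions) == 2

    def test_irreconcilable_rows_raise(self):
        rows = [CalibrationRow(Pose(0.0, 100.0, -900.0), L1=100.0),
                CalibrationRow(Pose(0.0, 100.0, -900.0), L1=2000.0)]
        with pytest.raises(CalibrationError):
            calibrate_lumped_offsets(rows, use_branches=(1,))

    def test_no_observations_raise(self):
        with pytest.raises(CalibrationError):
            calibrate_lumped_offsets([CalibrationRow(Pose(0, 0, -900))])


class TestTrajectoryCommands:
    def test_vertical_verification_motion(self):
        traj = gen_trajectory("adams_vertical")
        commands = trajectory_commands(LUMPED, traj)
        assert len(commands) == 10
        assert commands[-1].t == pytest.approx(5.0)
        last_pose = traj[-1].pose
        assert (last_pose.px, last_pose.py, last_pose.pz) == (0.0, 485.0,
                                                              -925.0)
        for c in commands:
            assert c.b1[1] == 0.0    # branches 1-2 stay in the XZ plane
            assert c.b2[1] == 0.0
            assert c.b3[0] == 0.0    # branch 3 stays in the YZ plane

    def test_constant_pose_gives_constant_lengths(self):
        pose = Pose(100.0, 200.0, -1000.0)
        traj = [TrajectorySample(0.5 * i, pose) for i in range(1, 5)]
        commands = trajectory_commands(LUMPED, traj)
        first = commands[0].lengths
        for c in commands[1:]:
            assert c.lengths == first

    def test_unreachable_sample_names_time(self):
        traj = [TrajectorySample(0.5, Pose(0.0, 100.0, -900.0)),
                TrajectorySample(1.0, Pose(-340.0, 100.0, 0.0))]
        with pytest.raises(InfeasiblePoseError, match="t=1.0"):
            trajectory_commands(LUMPED, traj)
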
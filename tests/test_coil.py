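import numpy as np
import pytest

from tmsfield.coil import (CoilModel, CoilPose, DegenerateFrameError,
                           DegenerateLoiError, SWEEP_ANGLES_DEG, build_sweep,
                           coil_dipoles, initial_pose, loi_orientations,
                           rotate_pose)
from tmsfield.engine import efield_sphere


def _lateral_pose():
    """Pose on the left lateral surface of the unperturbed scalp sphere."""
    n = np.array([-1.0, 1.0, 1.0])
    n /= np.linalg.norm(n)
    return initial_pose(n * 85.0, n)


class TestCoilModel:
    def test_same_sense_windings_rejected(self):
        with pytest.raises(ValueError):
            CoilModel(winding_sense=(1, 1))

    def test_minimal_discretization_two_opposed_dipoles(self):
        coil = CoilModel(dipoles_per_wing=1)
        pos, mom = coil_dipoles(coil, _lateral_pose())
        assert pos.shape == (2, 3) and mom.shape == (2, 3)
        assert np.allclose(mom[0], -mom[1])
        assert np.linalg.norm(mom[0]) == pytest.approx(
            coil.turns_per_wing * np.pi * 0.035**2)

    def test_total_moment_vanishes(self):
        pos, mom = coil_dipoles(CoilModel(), _lateral_pose())
        assert np.allclose(mom.sum(axis=0), 0.0, atol=1e-18)

    def test_dipoles_in_tangent_plane(self):
        pose = _lateral_pose()
        pos, _ = coil_dipoles(CoilModel(), pose)
        offsets = pos - pose.center
        assert np.abs(offsets @ pose.contact_normal).max() < 1e-9

    def test_half_turn_preserves_field_magnitudes(self, rng):
        """Rotating the pose 180 degrees about the coil-target axis swaps
        the wings; field magnitudes at arbitrary interior points are
        unchanged (figure-8 antisymmetry)."""
        pose = _lateral_pose()
        target = pose.center * 73.0 / 85.0
        coil = CoilModel()
        pts = rng.normal(size=(10, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * \
            rng.uniform(20, 70, size=(10, 1))
        e0 = efield_sphere(coil_dipoles(coil, pose), pts, 1.0, np.zeros(3))
        e1 = efield_sphere(coil_dipoles(coil, rotate_pose(pose, 180.0, target)),
                           pts, 1.0, np.zeros(3))
        assert np.allclose(e0.magnitudes(), e1.magnitudes(), rtol=1e-9)


class TestInitialPose:
    def test_posterolateral_signs(self):
        pose = _lateral_pose()
        assert pose.handle_dir @ np.array([0.0, -1.0, 0.0]) > 0
        assert pose.handle_dir @ np.array([-1.0, 0.0, 0.0]) > 0

    def test_handle_tangent_to_scalp(self):
        pose = _lateral_pose()
        assert abs(pose.handle_dir @ pose.contact_normal) < 1e-9

    def test_horizontal_projection_at_45_degrees(self):
        pose = _lateral_pose()
        h = pose.handle_dir.copy()
        h[2] = 0.0
        h /= np.linalg.norm(h)
        # 45 degrees to the plane x=0 means |h_x| == |h_y|
        assert abs(abs(h[0]) - abs(h[1])) < 1e-9

    def test_degenerate_horizontal_normal_rejected(self):
        with pytest.raises(DegenerateFrameError):
            initial_pose(np.array([-85.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]))


class TestRotatePose:
    def test_identity(self):
        pose = _lateral_pose()
        target = pose.center * 73.0 / 85.0
        r = rotate_pose(pose, 0.0, target)
        assert np.allclose(r.handle_dir, pose.handle_dir)
        assert r.rotation_deg == pose.rotation_deg

    def test_full_turn_periodicity(self):
        pose = _lateral_pose()
        target = pose.center * 73.0 / 85.0
        r = rotate_pose(pose, 360.0, target)
        assert np.allclose(r.handle_dir, pose.handle_dir, atol=1e-9)
        assert np.allclose(r.contact_normal, pose.contact_normal, atol=1e-9)

    def test_composition(self):
        pose = _lateral_pose()
        target = pose.center * 73.0 / 85.0
        two_steps = rotate_pose(rotate_pose(pose, 30.0, target), 30.0, target)
        one_step = rotate_pose(pose, 60.0, target)
        assert np.allclose(two_steps.handle_dir, one_step.handle_dir, atol=1e-9)
        assert two_steps.rotation_deg == pytest.approx(one_step.rotation_deg)

    def test_zero_axis_rejected(self):
        pose = _lateral_pose()
        with pytest.raises(ValueError):
            rotate_pose(pose, 30.0, pose.center)


class TestSweep:
    def test_structure(self):
        pose = _lateral_pose()
        sweep = build_sweep(pose, pose.center * 73.0 / 85.0)
        assert sweep.angles_deg == SWEEP_ANGLES_DEG
        assert len(sweep.poses) == 6
        assert len(sweep.mirror_partner) == 6
        assert sweep.mirror_partner[-30.0] == 150.0
        for mirrored, partner in sweep.mirror_partner.items():
            assert mirrored == partner - 180.0

    def test_mirrored_angle_field_equivalence(self, rng):
        """The field magnitude at any interior point is identical for an
        explicit angle and its mirror partner, licensing the shortcut."""
        pose = _lateral_pose()
        target = pose.center * 73.0 / 85.0
        coil = CoilModel()
        pts = rng.normal(size=(5, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 60.0
        for angle in (30.0, 90.0):
            e_pos = efield_sphere(
                coil_dipoles(coil, rotate_pose(pose, angle, target)),
                pts, 1.0, np.zeros(3))
            e_neg = efield_sphere(
                coil_dipoles(coil, rotate_pose(pose, angle - 180.0, target)),
                pts, 1.0, np.zeros(3))
            assert np.allclose(e_pos.magnitudes(), e_neg.magnitudes(),
                               rtol=1e-9)


class TestLoiOrientations:
    def test_orthogonal_handles(self):
        pose = _lateral_pose()
        func = pose.center * 73.0 / 85.0
        anat = func + np.array([0.0, 24.0, 0.0])
        par, perp, frame = loi_orientations(func, anat, pose)
        assert abs(par.handle_dir @ perp.handle_dir) < 1e-9
        assert abs(frame.tangent_loi @ frame.tangent_perp) < 1e-9
        assert abs(frame.tangent_loi @ pose.contact_normal) < 1e-9

    def test_tangent_loi_fixed_point(self):
        pose = _lateral_pose()
        func = pose.center * 73.0 / 85.0
        # LOI already in the tangent plane
        loi = np.cross(pose.contact_normal, np.array([0.0, 0.0, 1.0]))
        loi /= np.linalg.norm(loi)
        par, _, frame = loi_orientations(func, func - 20.0 * loi, pose)
        assert np.allclose(frame.tangent_loi, frame.loi_dir, atol=1e-9)
        assert np.allclose(par.handle_dir, loi, atol=1e-9)

    def test_degenerate_loi_rejected(self):
        pose = _lateral_pose()
        func = pose.center * 73.0 / 85.0
        with pytest.raises(DegenerateLoiError):
            loi_orientations(func, func, pose)
        with pytest.raises(DegenerateLoiError):
            loi_orientations(func, func - 10.0 * pose.contact_normal, pose)

    def test_perp_sign_choice_field_equivalent(self, rng):
        """The two possible signs of the perpendicular handle give identical
        field magnitudes (figure-8 symmetry)."""
        pose = _lateral_pose()
        func = pose.center * 73.0 / 85.0
        anat = func + np.array([3.0, 20.0, -5.0])
        _, perp, _ = loi_orientations(func, anat, pose)
        flipped = CoilPose(perp.center, perp.contact_normal, -perp.handle_dir)
        coil = CoilModel()
        pts = rng.normal(size=(5, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True) * 65.0
        e0 = efield_sphere(coil_dipoles(coil, perp), pts, 1.0, np.zeros(3))
        e1 = efield_sphere(coil_dipoles(coil, flipped), pts, 1.0, np.zeros(3))
        assert np.allclose(e0.magnitudes(), e1.magnitudes(), rtol=1e-9)
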
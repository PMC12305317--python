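import numpy as np
import pytest

from tmsfield.engine import FieldMap, normalize_to_m1
from tmsfield.roi import (RatioProfile, RoiResolutionError, define_roi, e_perp,
                          e_roi, orientation_histogram)


def _uniform_fieldmap(points, vectors, ref=1.0):
    f = FieldMap(sample_points=points, e_vectors=vectors, didt=1.0)
    return normalize_to_m1(f, ref)


class TestDefineRoi:
    def test_tiny_radius_keeps_center_vertex(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[100]
        roi = define_roi(v, dense_head.cortex_mesh, radius=0.5)
        assert roi.voxel_count == 1
        assert np.allclose(roi.sample_points[0], v)

    def test_count_matches_spherical_cap_area(self, dense_head, rng):
        """Voxel count approximates uniform density times the spherical-cap
        area.  Single centers fluctuate with the icosphere's pentagon-site
        density variation; the mean over random centers is tighter."""
        mesh = dense_head.cortex_mesh
        theta = 2.0 * np.arcsin(5.0 / 73.0)  # Euclidean 10-mm ball on r=73
        expected = len(mesh.vertices) * (1.0 - np.cos(theta)) / 2.0
        counts = []
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            roi = define_roi(d * 73.0, mesh, radius=10.0)
            counts.append(roi.voxel_count)
            assert abs(roi.voxel_count / expected - 1.0) < 0.15
        assert abs(np.mean(counts) / expected - 1.0) < 0.10

    def test_antipodal_centers_equal_count(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[7]
        a = define_roi(v, dense_head.cortex_mesh, radius=10.0)
        b = define_roi(-v, dense_head.cortex_mesh, radius=10.0)
        assert a.voxel_count == b.voxel_count

    def test_all_samples_within_radius(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[500]
        roi = define_roi(v, dense_head.cortex_mesh, radius=10.0)
        d = np.linalg.norm(roi.sample_points - v, axis=1)
        assert (d <= 10.0 + 1e-9).all()
        assert roi.voxel_count == len(roi.sample_points)

    def test_unresolvable_roi_rejected(self, small_head):
        far = np.array([0.0, 0.0, 300.0])
        with pytest.raises(RoiResolutionError):
            define_roi(far, small_head.cortex_mesh, radius=1.0)


class TestRoiMetrics:
    def test_uniform_field_at_reference_gives_unity(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[100]
        roi = define_roi(v, dense_head.cortex_mesh, radius=10.0)
        vec = np.tile([2.0, 0.0, 0.0], (roi.voxel_count, 1))
        fmap = _uniform_fieldmap(roi.sample_points, vec, ref=2.0)
        assert e_roi(roi, fmap) == pytest.approx(1.0)

    def test_linearity_in_field_scale(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[100]
        roi = define_roi(v, dense_head.cortex_mesh, radius=10.0)
        vec = np.tile([1.0, 0.5, 0.0], (roi.voxel_count, 1))
        a = e_roi(roi, _uniform_fieldmap(roi.sample_points, vec))
        b = e_roi(roi, _uniform_fieldmap(roi.sample_points, 0.8 * vec))
        assert b == pytest.approx(0.8 * a)

    def test_missing_normalization_rejected(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[100]
        roi = define_roi(v, dense_head.cortex_mesh, radius=10.0)
        fmap = FieldMap(roi.sample_points,
                        np.zeros_like(roi.sample_points), 1.0)
        with pytest.raises(ValueError):
            e_roi(roi, fmap)

    def test_tangent_field_has_zero_normal_component(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[100]
        roi = define_roi(v, dense_head.cortex_mesh, radius=10.0)
        up = np.array([0.0, 0.0, 1.0])
        tangent = np.cross(roi.normals, np.tile(up, (roi.voxel_count, 1)))
        fmap = _uniform_fieldmap(roi.sample_points, tangent)
        assert e_perp(roi, fmap) == pytest.approx(0.0, abs=1e-12)

    def test_normal_field_at_reference_gives_unity(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[100]
        roi = define_roi(v, dense_head.cortex_mesh, radius=10.0)
        fmap = _uniform_fieldmap(roi.sample_points, 3.0 * roi.normals, ref=3.0)
        assert e_perp(roi, fmap) == pytest.approx(1.0)
        # signed averaging agrees when the field is aligned with the normals
        assert e_perp(roi, fmap, signed=True) == pytest.approx(1.0)

    def test_e_perp_never_exceeds_e_roi(self, dense_head, rng):
        v = np.asarray(dense_head.cortex_mesh.vertices)[100]
        roi = define_roi(v, dense_head.cortex_mesh, radius=10.0)
        for _ in range(5):
            vec = rng.normal(size=(roi.voxel_count, 3))
            fmap = _uniform_fieldmap(roi.sample_points, vec)
            assert e_perp(roi, fmap) <= e_roi(roi, fmap) + 1e-12


class TestRatioProfileAndHistogram:
    @staticmethod
    def _profile(sid, rroi, rperp, angles=(0.0, 30.0, 60.0, 90.0, 120.0, 150.0)):
        rroi, rperp = np.asarray(rroi, float), np.asarray(rperp, float)
        ang = np.asarray(angles)
        return RatioProfile(
            sid, tuple(angles), rroi, rperp,
            float(ang[np.argmax(rroi)]), float(ang[np.argmin(rroi)]),
            float(ang[np.argmax(rperp)]), float(ang[np.argmin(rperp)]))

    def test_coincident_rois_give_unit_ratios(self, dense_head):
        from tmsfield.coil import CoilModel, build_sweep, coil_dipoles, initial_pose
        from tmsfield.engine import efield_sphere
        from tmsfield.roi import ratio_profile

        n = np.array([-1.0, 1.0, 1.0])
        n /= np.linalg.norm(n)
        pose = initial_pose(n * 85.0, n)
        target = n * 73.0
        roi = define_roi(
            np.asarray(dense_head.cortex_mesh.vertices)[
                np.argmin(np.linalg.norm(dense_head.cortex_mesh.vertices - target,
                                         axis=1))],
            dense_head.cortex_mesh, radius=10.0)
        coil = CoilModel()

        def evaluate(p, pts):
            return normalize_to_m1(
                efield_sphere(coil_dipoles(coil, p), pts, 0.8, np.zeros(3)), 1.0)

        prof = ratio_profile("s", build_sweep(pose, target), evaluate, roi, roi)
        assert np.allclose(prof.ratio_e_roi, 1.0)
        assert np.allclose(prof.ratio_e_perp, 1.0)

    def test_extrema_ties_break_toward_smaller_angle(self):
        p = self._profile("s", [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                          [2.0, 1.0, 2.0, 1.0, 2.0, 1.0])
        assert p.argmax_deg == 0.0 and p.argmin_deg == 0.0
        assert p.argmax_perp_deg == 0.0 and p.argmin_perp_deg == 30.0

    def test_single_subject_histogram_degenerate(self):
        p = self._profile("s", [1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        hmax, hmin = orientation_histogram([p], "e_roi")
        assert hmax[150.0] == 100.0 and hmin[0.0] == 100.0
        assert sum(hmax.values()) == pytest.approx(100.0)

    def test_histogram_sums_to_100(self):
        profiles = [self._profile(f"s{i}", np.roll([1, 2, 3, 4, 5, 6], i),
                                  np.roll([6, 5, 4, 3, 2, 1], i))
                    for i in range(7)]
        for metric in ("e_roi", "e_perp"):
            hmax, hmin = orientation_histogram(profiles, metric)
            assert sum(hmax.values()) == pytest.approx(100.0, abs=1e-9)
            assert sum(hmin.values()) == pytest.approx(100.0, abs=1e-9)

    def test_identical_subjects_concentrate(self):
        profiles = [self._profile(f"s{i}", [1, 2, 6, 4, 5, 3],
                                  [1, 2, 6, 4, 5, 3]) for i in range(5)]
        hmax, _ = orientation_histogram(profiles)
        assert hmax[60.0] == 100.0
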
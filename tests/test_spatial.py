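import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from tmsfield.spatial import (closest_point_on_mesh, compute_scd, dispersion,
                              pair_distances, project_to_cortex, scalp_entry,
                              surface_normal_at)
from tmsfield.cohort import TargetRecord, TargetSet

from .oracles import nearest_vertex, ray_march_scd


class TestProjection:
    def test_vertex_is_fixed_point(self, small_head):
        v = np.asarray(small_head.cortex_mesh.vertices)[17]
        p = project_to_cortex(v, small_head.cortex_mesh)
        assert np.linalg.norm(p - v) < 1e-9

    def test_center_projects_to_cortex_radius(self, small_head):
        p = project_to_cortex(np.zeros(3), small_head.cortex_mesh)
        # faces are chords, so the polyhedral surface sits just inside r=73
        assert 72.5 <= np.linalg.norm(p) <= 73.0 + 1e-9

    def test_beats_every_vertex(self, small_head, rng):
        """Nearest surface point is at least as close as the brute-force
        nearest vertex, for 100 random query points."""
        pts = rng.normal(size=(100, 3)) * 40.0
        proj, dist, _ = closest_point_on_mesh(pts, small_head.cortex_mesh)
        for p, d in zip(pts, dist):
            _, dv = nearest_vertex(p, small_head.cortex_mesh)
            assert d <= dv + 1e-9

    def test_idempotent(self, perturbed_head, rng):
        for p in rng.normal(size=(10, 3)) * 50.0:
            q = project_to_cortex(p, perturbed_head.cortex_mesh)
            q2 = project_to_cortex(q, perturbed_head.cortex_mesh)
            assert np.linalg.norm(q - q2) < 1e-9

    def test_empty_mesh_rejected(self, small_head):
        import trimesh

        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)),
                                faces=np.zeros((0, 3), dtype=int), process=False)
        with pytest.raises(ValueError):
            closest_point_on_mesh(np.zeros((1, 3)), empty)


class TestScalpEntry:
    def test_radial_geometry_unperturbed(self, dense_head):
        v = np.asarray(dense_head.cortex_mesh.vertices)[5]
        entry = scalp_entry(v, dense_head.scalp_mesh)
        # radial up to the facet tilt of the polyhedral scalp surface
        expected = v / np.linalg.norm(v) * 85.0
        assert np.linalg.norm(entry - expected) < 0.3

    def test_matches_brute_force_oracle(self, perturbed_head, rng):
        verts = np.asarray(perturbed_head.cortex_mesh.vertices)
        for i in rng.integers(0, len(verts), size=10):
            entry = scalp_entry(verts[i], perturbed_head.scalp_mesh)
            _, dv = nearest_vertex(verts[i], perturbed_head.scalp_mesh)
            d = np.linalg.norm(entry - verts[i])
            assert d <= dv + 1e-9


class TestScd:
    def test_unperturbed_radii_difference(self, small_head):
        v = np.asarray(small_head.scalp_mesh.vertices)[40]
        scd = compute_scd(v, v / np.linalg.norm(v), small_head.cortex_mesh)
        # polyhedral faces sit inside the sphere: SCD in [12, 12 + sagitta]
        assert 11.99 <= scd <= 12.35

    def test_spherical_symmetry(self, dense_head, rng):
        scds = []
        for _ in range(10):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            sp, _, _ = closest_point_on_mesh((d * 85.0)[None, :],
                                             dense_head.scalp_mesh)
            n = surface_normal_at(sp[0], dense_head.scalp_mesh)
            scds.append(compute_scd(sp[0], n, dense_head.cortex_mesh))
        assert max(scds) - min(scds) < 0.05

    def test_matches_ray_march_oracle(self, perturbed_head, rng):
        for _ in range(2):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            sp, _, _ = closest_point_on_mesh((d * 85.0)[None, :],
                                             perturbed_head.scalp_mesh)
            n = surface_normal_at(sp[0], perturbed_head.scalp_mesh)
            scd = compute_scd(sp[0], n, perturbed_head.cortex_mesh)
            oracle = ray_march_scd(sp[0], -n, perturbed_head.cortex_mesh,
                                   step=0.05)
            assert oracle is not None
            assert abs(scd - oracle) < 0.05


class TestDispersion:
    def test_identical_points_zero(self):
        s = dispersion(np.tile([1.0, 2.0, 3.0], (7, 1)))
        assert s.mean_mm == 0.0 and s.sd_mm == 0.0

    def test_two_points_mean_half_distance(self):
        s = dispersion(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        assert s.mean_mm == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dispersion(np.zeros((0, 3)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance(self, seed):
        """Dispersion is unchanged by any rotation + translation and scales
        linearly under uniform scaling."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 3)) * 20.0
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3) * 100.0
        moved = pts @ rot.T + shift
        d0 = dispersion(pts)
        d1 = dispersion(moved)
        assert d1.mean_mm == pytest.approx(d0.mean_mm, abs=1e-9)
        scale = 2.5
        d2 = dispersion(pts * scale)
        assert d2.mean_mm == pytest.approx(scale * d0.mean_mm, rel=1e-12)


class TestPairDistances:
    @staticmethod
    def _subject(sid, f, a, e):
        mk = lambda p: TargetRecord(np.asarray(p, float), np.zeros(3), 0.0)
        return TargetSet(sid, mk(f), mk(a), mk(e))

    def test_coincident_targets_zero(self):
        cohort = [self._subject("s1", [1, 2, 3], [1, 2, 3], [1, 2, 3])] * 3
        for s in pair_distances(cohort):
            assert s.mean_mm == 0.0

    def test_hand_computed_two_subjects(self):
        cohort = [
            self._subject("s1", [0, 0, 0], [3, 4, 0], [0, 0, 12]),
            self._subject("s2", [1, 0, 0], [1, 0, 5], [1, 12, 5]),
        ]
        out = {s.pair: s for s in pair_distances(cohort)}
        assert out[("functional", "anatomical")].per_subject_distance == \
            pytest.approx([5.0, 5.0])
        assert out[("anatomical", "f3")].per_subject_distance == \
            pytest.approx([13.0, 12.0])
        assert out[("functional", "f3")].mean_mm == pytest.approx(
            (12.0 + 13.0) / 2.0)

    def test_calibrated_cohort_ordering(self, default_cohort):
        """Functional-anatomical separation exceeds anatomical-F3, as in the
        measured cohort."""
        out = {s.pair: s.mean_mm for s in pair_distances(default_cohort)}
        assert out[("functional", "anatomical")] > out[("anatomical", "f3")]
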
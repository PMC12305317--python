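"""ROI field metrics: E_ROI, E_perp, voxel counts and orientation ratios.

A region of interest is the set of cortical-surface samples within a
10-mm-radius sphere centered on a cortical target.  In the synthetic
surface model "voxels" are those surface samples; a gray-matter-thickness
volume estimate is reported alongside the count.  E_ROI is the mean field
magnitude over the ROI normalized by the motor-cortex reference field;
E_perp is the corresponding mean (unsigned by default) normal component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .engine import FieldMap

__all__ = [
    "Roi",
    "RoiFieldMetrics",
    "RatioProfile",
    "RoiResolutionError",
    "define_roi",
    "e_roi",
    "e_perp",
    "ratio_profile",
    "orientation_histogram",
    "GM_THICKNESS_MM",
]

#: Assumed gray-matter thickness used for the ROI volume estimate.
GM_THICKNESS_MM = 2.5


class RoiResolutionError(ValueError):
    """No cortical sample falls inside the ROI; use a denser mesh."""


@dataclass
class Roi:
    """Spherical cortical ROI realized as surface samples."""

    center: np.ndarray
    radius: float
    sample_points: np.ndarray   # (K, 3) mm
    normals: np.ndarray         # (K, 3) outward unit normals
    sample_indices: np.ndarray  # vertex indices into the cortex mesh
    voxel_count: int
    volume_mm3: float


@dataclass
class RoiFieldMetrics:
    """Normalized ROI metrics at one coil orientation."""

    e_roi: float
    e_perp: float
    orientation_deg: float
    target_type: str


@dataclass
class RatioProfile:
    """Functional/anatomical metric ratios across the orientation sweep."""

    subject_id: str
    angles_deg: tuple[float, ...]
    ratio_e_roi: np.ndarray
    ratio_e_perp: np.ndarray
    argmax_deg: float
    argmin_deg: float
    argmax_perp_deg: float
    argmin_perp_deg: float


def define_roi(center: np.ndarray, cortex_mesh: trimesh.Trimesh,
               radius: float = 10.0) -> Roi:
    """Collect cortical vertices within ``radius`` mm of ``center``.

    Membership is Euclidean (a true sphere, not a geodesic disc).  The
    volume estimate multiplies the member vertices' share of the surface
    area by an assumed gray-matter thickness of ``GM_THICKNESS_MM``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, float)
    verts = np.asarray(cortex_mesh.vertices, float)
    d = np.linalg.norm(verts - center, axis=1)
    idx = np.flatnonzero(d <= radius)
    if idx.size == 0:
        # the center itself may lie on a face; fall back to nearest vertex
        nearest = int(np.argmin(d))
        if d[nearest] <= radius:
            idx = np.array([nearest])
        else:
            raise RoiResolutionError(
                f"no cortical vertex within {radius} mm of the ROI center; "
                "increase mesh density")
    normals = np.asarray(cortex_mesh.vertex_normals, float)[idx]
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    # vertex area share: one third of each incident face
    face_area = cortex_mesh.area_faces
    vert_area = np.zeros(len(verts))
    np.add.at(vert_area, np.asarray(cortex_mesh.faces).ravel(),
              np.repeat(face_area / 3.0, 3))
    volume = float(vert_area[idx].sum() * GM_THICKNESS_MM)
    return Roi(center=center, radius=float(radius), sample_points=verts[idx],
               normals=normals, sample_indices=idx, voxel_count=int(idx.size),
               volume_mm3=volume)


def _roi_field_rows(roi: Roi, fieldmap: FieldMap) -> np.ndarray:
    """Rows of ``fieldmap.e_vectors`` matching the ROI samples."""
    if fieldmap.m1_reference is None:
        raise ValueError("fieldmap has no m1_reference; call normalize_to_m1 first")
    tree = cKDTree(fieldmap.sample_points)
    dist, rows = tree.query(roi.sample_points)
    if np.any(dist > 1e-6):
        raise ValueError("ROI samples are not all present in the field map")
    return fieldmap.e_vectors[rows]


def e_roi(roi: Roi, fieldmap: FieldMap) -> float:
    """Mean field magnitude over the ROI divided by the M1 reference."""
    e = _roi_field_rows(roi, fieldmap)
    return float(np.linalg.norm(e, axis=1).mean() / fieldmap.m1_reference)


def e_perp(roi: Roi, fieldmap: FieldMap, signed: bool = False) -> float:
    """Mean normal field component over the ROI divided by the M1 reference.

    Unsigned (|E . n|) by default; ``signed=True`` averages the signed
    component instead.
    """
    e = _roi_field_rows(roi, fieldmap)
    comp = np.einsum("ij,ij->i", e, roi.normals)
    if not signed:
        comp = np.abs(comp)
    return float(comp.mean() / fieldmap.m1_reference)


def ratio_profile(subject_id: str, sweep, evaluate,
                  functional_roi: Roi, anatomical_roi: Roi) -> RatioProfile:
    """Functional/anatomical E_ROI and E_perp ratios across the sweep.

    ``evaluate(pose, points) -> FieldMap`` is the field engine bound to
    the subject (coil above the functional target's scalp entry, with the
    M1 reference attached).  Ratios use only the explicit 0..150-degree
    poses; mirrored angles share their partners' values exactly.  Extrema
    ties break toward the smaller angle.
    """
    points = np.vstack([functional_roi.sample_points, anatomical_roi.sample_points])
    r_roi, r_perp = [], []
    for pose in sweep.poses:
        fmap = evaluate(pose, points)
        num, den = e_roi(functional_roi, fmap), e_roi(anatomical_roi, fmap)
        if den <= 0:
            raise ValueError("zero anatomical-target field; degenerate geometry")
        r_roi.append(num / den)
        den_p = e_perp(anatomical_roi, fmap)
        if den_p <= 0:
            raise ValueError("zero anatomical-target normal field")
        r_perp.append(e_perp(functional_roi, fmap) / den_p)
    r_roi, r_perp = np.asarray(r_roi), np.asarray(r_perp)
    ang = np.asarray(sweep.angles_deg)
    return RatioProfile(
        subject_id=subject_id, angles_deg=tuple(sweep.angles_deg),
        ratio_e_roi=r_roi, ratio_e_perp=r_perp,
        argmax_deg=float(ang[int(np.argmax(r_roi))]),
        argmin_deg=float(ang[int(np.argmin(r_roi))]),
        argmax_perp_deg=float(ang[int(np.argmax(r_perp))]),
        argmin_perp_deg=float(ang[int(np.argmin(r_perp))]),
    )


def orientation_histogram(profiles: list[RatioProfile], metric: str = "e_roi"
                          ) -> tuple[dict[float, float], dict[float, float]]:
    """Percent of subjects whose ratio peaks (resp. bottoms) at each angle.

    Returns (max_histogram, min_histogram); each maps every sweep angle to
    a percentage, and each histogram sums to 100.
    """
    if not profiles:
        raise ValueError("no profiles")
    angles = profiles[0].angles_deg
    attr_max = "argmax_deg" if metric == "e_roi" else "argmax_perp_deg"
    attr_min = "argmin_deg" if metric == "e_roi" else "argmin_perp_deg"
    n = len(profiles)
    hmax = {a: 100.0 * sum(getattr(p, attr_max) == a for p in profiles) / n
            for a in angles}
    hmin = {a: 100.0 * sum(getattr(p, attr_min) == a for p in profiles) / n
            for a in angles}
    return hmax, hmin
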
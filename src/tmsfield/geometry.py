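"""Synthetic layered-sphere head models.

A head is a family of concentric, optionally perturbed, triangulated
spherical surfaces (scalp, skull, CSF, cortex).  The perturbation is a
smooth low-order radial displacement field, so surface normals deviate
from the purely radial direction and nearest-surface / ray logic
downstream is exercised on non-trivial geometry.  Tissue conductivities
are carried as metadata: the induced E-field inside a spherically
symmetric conductor is independent of the radial conductivity profile,
so the field engine never reads them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.special import sph_harm_y

__all__ = [
    "DEFAULT_LAYER_RADII",
    "TISSUE_CONDUCTIVITY_S_PER_M",
    "DEFAULT_F3_ARC",
    "HeadGeometry",
    "InvalidGeometryError",
    "generate_head",
    "place_f3",
]

#: Nominal layer radii in mm (outermost to innermost).
DEFAULT_LAYER_RADII = {"scalp": 85.0, "skull": 80.0, "csf": 75.0, "cortex": 73.0}

#: Literature tissue conductivities in S/m, metadata only (see module docstring).
TISSUE_CONDUCTIVITY_S_PER_M = {
    "scalp": 0.465,
    "skull": 0.010,
    "csf": 1.654,
    "cortex": 0.275,  # gray matter
    "white_matter": 0.126,
}

#: Default (azimuth, elevation) arc fractions for the F3-analog scalp site in
#: the synthetic 10-20-like frame; chosen so its cortical projection lands at
#: the DLPFC anatomical reference direction (left-anterior-superior octant).
DEFAULT_F3_ARC = (0.1134, 0.2679)


class InvalidGeometryError(ValueError):
    """Raised when requested layer radii are not strictly decreasing."""


@dataclass
class HeadGeometry:
    """Concentric perturbed-sphere head model.

    Attributes
    ----------
    center : (3,) ndarray
        Sphere center in mm (the shared origin of the RAS-like frame).
    layer_radii : dict
        Nominal radius per layer in mm, strictly decreasing
        scalp > skull > csf > cortex.
    scalp_mesh, cortex_mesh : trimesh.Trimesh
        Triangulated surfaces with vertices in mm.  Skull and CSF layers
        are carried as radii only; no downstream computation samples them.
    conductivities : dict
        Tissue conductivities in S/m (metadata).
    perturbation_amplitude : float
        Maximum absolute radial displacement in mm applied to each layer.
    """

    center: np.ndarray
    layer_radii: dict
    scalp_mesh: trimesh.Trimesh
    cortex_mesh: trimesh.Trimesh
    conductivities: dict = field(
        default_factory=lambda: dict(TISSUE_CONDUCTIVITY_S_PER_M)
    )
    perturbation_amplitude: float = 0.0

    def validate(self) -> None:
        """Check the geometric invariants, raising ``ValueError`` on failure."""
        radii = [self.layer_radii[k] for k in ("scalp", "skull", "csf", "cortex")]
        if not all(a > b for a, b in zip(radii, radii[1:])):
            raise InvalidGeometryError(f"layer radii not strictly decreasing: {radii}")
        for name in ("scalp", "cortex"):
            mesh = getattr(self, f"{name}_mesh")
            r = np.linalg.norm(mesh.vertices - self.center, axis=1)
            dev = np.abs(r - self.layer_radii[name]).max()
            if dev > self.perturbation_amplitude + 1e-6:
                raise ValueError(
                    f"{name} vertices deviate {dev:.3g} mm from nominal radius, "
                    f"more than the perturbation amplitude"
                )
            normals = mesh.vertex_normals
            outward = np.einsum("ij,ij->i", normals, mesh.vertices - self.center)
            if not (outward > 0).all():
                raise ValueError(f"{name} normals are not all outward")

    def vertex_normals(self, layer: str) -> np.ndarray:
        """Outward unit vertex normals of ``layer`` ('scalp' or 'cortex')."""
        mesh = getattr(self, f"{layer}_mesh")
        n = np.asarray(mesh.vertex_normals, dtype=float)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def save(self, path, layer: str = "cortex") -> None:
        """Export one layer mesh (format from the file suffix: off/ply/stl)."""
        getattr(self, f"{layer}_mesh").export(str(path))


def _smooth_radial_field(directions: np.ndarray, amplitude: float,
                         rng: np.random.Generator, max_degree: int = 3) -> np.ndarray:
    """Smooth band-limited radial displacement with max |field| == amplitude.

    Random real spherical-harmonic coefficients up to ``max_degree`` are
    drawn from ``rng`` and the resulting field is rescaled so its maximum
    absolute value over the supplied unit directions equals ``amplitude``.
    """
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    out = np.zeros(len(directions))
    for l in range(1, max_degree + 1):
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            out += rng.normal() * y.real
            if m > 0:
                out += rng.normal() * y.imag
    peak = np.abs(out).max()
    if peak == 0:
        return out
    return out * (amplitude / peak)


def generate_head(layer_radii: dict | None = None, mesh_density: int = 4,
                  perturbation_amplitude: float = 0.0, seed: int = 0,
                  center: np.ndarray | None = None) -> HeadGeometry:
    """Build a (perturbed) concentric-sphere head.

    Parameters
    ----------
    layer_radii : dict, optional
        Nominal radii in mm; defaults to :data:`DEFAULT_LAYER_RADII`.
    mesh_density : int
        Icosphere subdivision level (>= 3).  Level 4 gives 2562 vertices
        per surface, level 5 gives 10242.
    perturbation_amplitude : float
        Maximum radial displacement in mm.  Each meshed layer receives an
        independent smooth low-order displacement field.
    seed : int
        Seeds the displacement fields; two calls with the same arguments
        return bitwise-identical vertex arrays.

    Raises
    ------
    InvalidGeometryError
        If the radii are not strictly decreasing scalp > skull > csf > cortex.
    """
    radii = dict(DEFAULT_LAYER_RADII if layer_radii is None else layer_radii)
    ordered = [radii[k] for k in ("scalp", "skull", "csf", "cortex")]
    if not all(a > b for a, b in zip(ordered, ordered[1:])):
        raise InvalidGeometryError(f"layer radii not strictly decreasing: {ordered}")
    if mesh_density < 3:
        raise ValueError("mesh_density must be >= 3")
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)

    unit = trimesh.creation.icosphere(subdivisions=mesh_density, radius=1.0)
    directions = np.asarray(unit.vertices, dtype=float)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    meshes = {}
    for name in ("scalp", "cortex"):
        r = np.full(len(directions), radii[name])
        if perturbation_amplitude > 0:
            r = r + _smooth_radial_field(directions, perturbation_amplitude, rng)
        verts = center + directions * r[:, None]
        meshes[name] = trimesh.Trimesh(vertices=verts, faces=unit.faces.copy(),
                                       process=False)

    head = HeadGeometry(
        center=center,
        layer_radii=radii,
        scalp_mesh=meshes["scalp"],
        cortex_mesh=meshes["cortex"],
        perturbation_amplitude=float(perturbation_amplitude),
    )
    head.validate()
    return head


def place_f3(head: HeadGeometry, arc_parameters: tuple[float, float] = DEFAULT_F3_ARC
             ) -> np.ndarray:
    """Scalp point of the F3-analog electrode in the synthetic 10-20 frame.

    The frame is anchored at synthetic nasion (+y, z=0), inion (-y) and
    vertex (+z) poles of the scalp sphere.  ``arc_parameters`` are
    (azimuth_fraction, elevation_fraction), both clamped to [0, 1]:
    elevation 1 is the vertex; azimuth is the fraction of a full turn from
    the nasion meridian rotating toward the left (-x) hemisphere.  The
    returned point lies on the scalp mesh (nearest surface point of the
    ideal direction), deterministically.
    """
    from .spatial import closest_point_on_mesh  # local import, avoids cycle

    az = float(np.clip(arc_parameters[0], 0.0, 1.0))
    el = float(np.clip(arc_parameters[1], 0.0, 1.0))
    polar = (1.0 - el) * np.pi / 2.0  # 0 at vertex, pi/2 on the equator
    phi = az * 2.0 * np.pi
    direction = np.array([
        -np.sin(polar) * np.sin(phi),
        np.sin(polar) * np.cos(phi),
        np.cos(polar),
    ])
    probe = head.center + direction * head.layer_radii["scalp"]
    point, _, _ = closest_point_on_mesh(probe[None, :], head.scalp_mesh)
    return point[0]
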
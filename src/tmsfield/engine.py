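"""Analytical E-field of magnetic dipoles outside a spherical conductor.

For a spherically symmetric volume conductor the quasistatic E-field
induced inside by external time-varying magnetic dipoles has a closed
form, obtained from the Sarvas magnetoencephalography formula by
reciprocity.  Two properties of that solution carry the whole analysis:
the total field is everywhere tangential (the secondary charge field
cancels the radial component exactly), and the result is independent of
the radial conductivity profile — which is why the tissue conductivities
of the head model are metadata only.

Positions are in mm and converted internally to SI; ``didt`` is the coil
current slew rate in A/us; fields are returned in V/m.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["FieldMap", "efield_sphere", "normalize_to_m1", "DomainError"]

_MU0_OVER_4PI = 1e-7  # T m / A


class DomainError(ValueError):
    """Sample points outside the conductor, or dipoles inside it."""


@dataclass
class FieldMap:
    """E-field vectors evaluated at a set of sample points.

    ``m1_reference`` is the scalar reference field (V/m) at the
    motor-cortex analog used to express downstream ROI metrics as
    dimensionless fractions of the motor-threshold field; it is metadata
    and the raw vectors stay in V/m.
    """

    sample_points: np.ndarray  # (N, 3) mm
    e_vectors: np.ndarray      # (N, 3) V/m
    didt: float                # A/us
    m1_reference: float | None = None

    def __post_init__(self):
        self.sample_points = np.atleast_2d(np.asarray(self.sample_points, float))
        self.e_vectors = np.atleast_2d(np.asarray(self.e_vectors, float))
        if len(self.sample_points) != len(self.e_vectors):
            raise ValueError("sample_points and e_vectors length mismatch")
        if self.didt < 0:
            raise ValueError("didt must be non-negative")

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.e_vectors, axis=1)


def efield_sphere(dipoles: tuple[np.ndarray, np.ndarray], sample_points: np.ndarray,
                  didt: float, sphere_center: np.ndarray,
                  conductor_radius: float | None = None) -> FieldMap:
    """Induced E-field at interior points of a spherically symmetric conductor.

    Parameters
    ----------
    dipoles : (positions, moments)
        Dipole positions in mm and unit-slew-rate moments in m^2 (turns x
        area, signed by winding sense); the effective moment rate is
        ``moments * didt``.
    sample_points : (N, 3) array, mm
        Evaluation points, strictly inside the conductor.
    didt : float
        Coil current slew rate in A/us.
    sphere_center : (3,) array, mm
        Center of the conductor; the solution depends on no other property
        of the conductor (radius and conductivity profile drop out).
    conductor_radius : float, optional
        If given, sample points are checked to lie strictly inside and
        dipole positions outside this radius (mm).

    Returns
    -------
    FieldMap with e_vectors in V/m.  E is linear in ``didt`` and exactly
    tangential: ``E . (r - center) == 0`` to machine precision.
    """
    positions, moments = dipoles
    positions = np.atleast_2d(np.asarray(positions, float))
    moments = np.atleast_2d(np.asarray(moments, float))
    sample_points = np.atleast_2d(np.asarray(sample_points, float))
    center = np.asarray(sphere_center, float)

    r_samples = np.linalg.norm(sample_points - center, axis=1)
    r_dip = np.linalg.norm(positions - center, axis=1)
    if conductor_radius is not None:
        if (r_samples >= conductor_radius).any():
            raise DomainError("sample point outside the conductor sphere")
        if (r_dip < conductor_radius - 1e-9).any():
            raise DomainError("dipole inside the conductor sphere")
    elif (r_samples.max() >= r_dip.min() - 1e-9):
        raise DomainError("sample points must be strictly deeper than every dipole")

    # SI, relative to the sphere center
    r0 = (sample_points - center)[:, None, :] * 1e-3    # field points  (N,1,3)
    rc = (positions - center)[None, :, :] * 1e-3        # dipoles       (1,M,3)
    mdot = moments[None, :, :] * (didt * 1e6)           # A m^2 / s

    a = rc - r0
    an = np.linalg.norm(a, axis=-1)
    rcn = np.linalg.norm(rc, axis=-1)
    dot_r0rc = np.sum(r0 * rc, axis=-1)
    F = an * (rcn * an + rcn**2 - dot_r0rc)
    adotrc = np.sum(a * rc, axis=-1)
    c1 = an**2 / rcn + adotrc / an + 2.0 * an + 2.0 * rcn
    c2 = an + 2.0 * rcn + adotrc / an
    gradF = c1[..., None] * rc - c2[..., None] * r0

    shape = np.broadcast_shapes(r0.shape, rc.shape)
    cross_r0_m = np.cross(np.broadcast_to(r0, shape), np.broadcast_to(mdot, shape))
    cross_r0_rc = np.cross(np.broadcast_to(r0, shape), np.broadcast_to(rc, shape))
    gFm = np.sum(gradF * mdot, axis=-1)
    e = (-_MU0_OVER_4PI / F[..., None] ** 2
         * (F[..., None] * cross_r0_m - gFm[..., None] * cross_r0_rc)).sum(axis=1)
    return FieldMap(sample_points=sample_points, e_vectors=e, didt=float(didt))


def normalize_to_m1(fieldmap: FieldMap, m1_field_value: float) -> FieldMap:
    """Attach the motor-cortex reference field to a FieldMap.

    ``m1_field_value`` is the field strength (V/m) at the M1-analog
    cortical site with the coil at the M1 scalp position, initial
    orientation and didt = 1 A/us.  Downstream normalized metrics divide
    by this reference; the raw vectors are unchanged and re-normalizing
    simply overwrites the metadata.
    """
    if not m1_field_value > 0:
        raise ValueError("m1 reference field must be positive")
    return replace(fieldmap, m1_reference=float(m1_field_value))
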
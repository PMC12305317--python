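"""Independent oracles used to validate the package's numerics.

These deliberately avoid the implementation paths they check:

* :class:`HarmonicOracle` solves the interior Neumann boundary-value
  problem for the secondary potential of a homogeneous conducting sphere
  by spherical-harmonic expansion (degree <= 40) with quadrature on the
  surface and finite-difference gradients — no part of the closed-form
  reciprocity solution is reused.
* ``nearest_vertex`` is the brute-force nearest-mesh-vertex search.
* ``ray_march_scd`` measures the scalp-to-cortex distance by dense
  marching along the inward normal with sign checks against the mesh.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import sph_harm_y

MU0_4PI = 1e-7


def adot(x, dipole_pos, dipole_mdot):
    """-dA/dt source term of time-varying magnetic dipoles (SI units)."""
    x = np.atleast_2d(x)[:, None, :]
    pos = np.atleast_2d(dipole_pos)[None, :, :]
    md = np.atleast_2d(dipole_mdot)[None, :, :]
    r = x - pos
    rn = np.linalg.norm(r, axis=-1, keepdims=True)
    shape = np.broadcast_shapes(md.shape, r.shape)
    return (MU0_4PI * np.cross(np.broadcast_to(md, shape), r) / rn**3).sum(axis=1)


class HarmonicOracle:
    """Interior E-field of a homogeneous conducting sphere, by expansion.

    The secondary potential V is harmonic inside the sphere with Neumann
    condition dV/dr = -Adot_r on the surface; its coefficients are fitted
    by Gauss-Legendre x uniform-azimuth quadrature, and the E-field is
    E = -Adot - grad V with central-difference gradients.
    """

    def __init__(self, radius_m: float, degree: int = 40,
                 n_theta: int = 48, n_phi: int = 96):
        self.radius = radius_m
        x, w = leggauss(n_theta)
        theta = np.arccos(x)
        phi = np.arange(n_phi) * 2.0 * np.pi / n_phi
        th, ph = np.meshgrid(theta, phi, indexing="ij")
        self._th, self._ph = th.ravel(), ph.ravel()
        self._w = np.repeat(w, n_phi) * (2.0 * np.pi / n_phi)
        self._surface = radius_m * np.stack(
            [np.sin(self._th) * np.cos(self._ph),
             np.sin(self._th) * np.sin(self._ph),
             np.cos(self._th)], axis=-1)
        self._lms = [(l, m) for l in range(1, degree + 1)
                     for m in range(-l, l + 1)]
        self._ybar = np.stack([np.conj(sph_harm_y(l, m, self._th, self._ph))
                               for l, m in self._lms])

    def fit(self, dipole_pos, dipole_mdot):
        g = -np.einsum("ij,ij->i", adot(self._surface, dipole_pos, dipole_mdot),
                       self._surface / self.radius)
        proj = self._ybar @ (self._w * g)
        self._coef = np.array([self.radius / l for l, _ in self._lms]) * proj
        self._dip = (np.atleast_2d(dipole_pos), np.atleast_2d(dipole_mdot))

    def potential(self, x):
        x = np.atleast_2d(x)
        r = np.linalg.norm(x, axis=-1)
        th = np.arccos(np.clip(x[:, 2] / r, -1.0, 1.0))
        ph = np.arctan2(x[:, 1], x[:, 0])
        v = np.zeros(len(x), dtype=complex)
        for (l, m), c in zip(self._lms, self._coef):
            v += c * (r / self.radius) ** l * sph_harm_y(l, m, th, ph)
        return v.real

    def efield(self, x):
        x = np.atleast_2d(x)
        h = 1e-7
        grad = np.zeros_like(x, dtype=float)
        for axis in range(3):
            dx = np.zeros(3)
            dx[axis] = h
            grad[:, axis] = (self.potential(x + dx) - self.potential(x - dx)) / (2 * h)
        return -adot(x, *self._dip) - grad


def nearest_vertex(point, mesh):
    """Brute-force nearest mesh vertex and its distance."""
    verts = np.asarray(mesh.vertices, float)
    d = np.linalg.norm(verts - np.asarray(point, float), axis=1)
    i = int(np.argmin(d))
    return verts[i], float(d[i])


def ray_march_scd(scalp_point, inward_dir, cortex_mesh, max_dist=60.0,
                  step=0.01):
    """First cortex crossing along the ray, by dense marching.

    Uses signed distance to the closed cortex surface (outside->inside
    transition), bisected to ``step``/100 precision.
    """
    from tmsfield.spatial import closest_point_on_mesh

    p0 = np.asarray(scalp_point, float)
    d = np.asarray(inward_dir, float)
    d = d / np.linalg.norm(d)
    center = np.asarray(cortex_mesh.vertices, float).mean(axis=0)

    def inside(t):
        q = p0 + t * d
        cp, dist, _ = closest_point_on_mesh(q[None, :], cortex_mesh)
        # crude inside test adequate for star-shaped meshes
        r_q = np.linalg.norm(q - center)
        r_cp = np.linalg.norm(cp[0] - center)
        return r_q < r_cp

    ts = np.arange(0.0, max_dist, step)
    prev = inside(0.0)
    for t in ts[1:]:
        cur = inside(t)
        if cur and not prev:
            lo, hi = t - step, t
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                if inside(mid):
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)
        prev = cur
    return None
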
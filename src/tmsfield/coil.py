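"""Figure-8 coil model, poses, orientation sweeps and LOI-derived orientations.

The coil is a generic 70-mm figure-8: two opposed circular windings whose
centers are separated perpendicular to the handle axis, so that the induced
current under the junction runs parallel to the handle.  Each winding is
discretized as magnetic dipoles uniformly distributed over its disc (a
uniformly magnetized disc is equivalent to its boundary current loop), with
moments normal to the coil plane and signs set by the opposed winding
senses.

The initial clinical pose has the handle pointing posterolaterally at 45
degrees to the mid-sagittal plane; rotations are about the axis from the
coil center to the intracranial target.  Because the two windings are
equal and opposed, a 180-degree rotation flips the sign of the field but
not its magnitude, which licenses evaluating only 0..150 degrees and
reading the -180..-30 range off mirror partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CoilModel",
    "CoilPose",
    "OrientationSweep",
    "LoiFrame",
    "DegenerateFrameError",
    "DegenerateLoiError",
    "coil_dipoles",
    "initial_pose",
    "rotate_pose",
    "build_sweep",
    "loi_orientations",
    "SWEEP_ANGLES_DEG",
]

SWEEP_ANGLES_DEG = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)


class DegenerateFrameError(ValueError):
    """Scalp normal leaves no well-defined 45-degree tangent direction."""


class DegenerateLoiError(ValueError):
    """LOI is (numerically) parallel to the coil contact normal."""


@dataclass
class CoilModel:
    """Figure-8 coil geometry and discretization.

    wing_radius and wing_separation in mm; ``turns_per_wing`` scales the
    dipole moments (it cancels under M1 normalization); ``winding_sense``
    must be opposed for a figure-8.
    """

    wing_radius: float = 35.0
    wing_separation: float = 70.0
    turns_per_wing: int = 9
    dipoles_per_wing: int = 16
    winding_sense: tuple[int, int] = (1, -1)

    def __post_init__(self):
        if self.wing_radius <= 0:
            raise ValueError("wing_radius must be positive")
        if self.dipoles_per_wing < 1:
            raise ValueError("dipoles_per_wing must be >= 1")
        if self.winding_sense[0] * self.winding_sense[1] != -1:
            raise ValueError("figure-8 winding senses must be opposite")


@dataclass
class CoilPose:
    """Placement of the coil junction on the scalp.

    ``center`` is the junction point (mm), ``contact_normal`` the outward
    scalp normal there, ``handle_dir`` a unit vector in the tangent plane,
    and ``rotation_deg`` the angle relative to the initial orientation,
    wrapped to (-180, 180].
    """

    center: np.ndarray
    contact_normal: np.ndarray
    handle_dir: np.ndarray
    rotation_deg: float = 0.0

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        n = np.asarray(self.contact_normal, float)
        self.contact_normal = n / np.linalg.norm(n)
        h = np.asarray(self.handle_dir, float)
        h = h - (h @ self.contact_normal) * self.contact_normal
        norm = np.linalg.norm(h)
        if norm < 1e-12:
            raise ValueError("handle_dir parallel to contact_normal")
        self.handle_dir = h / norm
        self.rotation_deg = _wrap_angle(self.rotation_deg)


def _wrap_angle(deg: float) -> float:
    """Wrap to (-180, 180]."""
    w = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


@dataclass
class OrientationSweep:
    """Explicit poses at 0..150 degrees plus mirrored bookkeeping.

    ``mirror_partner`` maps each mirrored angle in -180..-30 to the
    explicit angle whose field magnitudes it shares (partner = angle + 180).
    """

    base_pose: CoilPose
    angles_deg: tuple[float, ...]
    poses: list[CoilPose]
    mirror_partner: dict[float, float] = field(default_factory=dict)


@dataclass
class LoiFrame:
    """Line-of-interest frame at the coil contact point.

    ``loi_dir`` points from the anatomical to the functional cortical
    target; ``tangent_loi`` is its unit projection into the coil tangent
    plane and ``tangent_perp`` the orthogonal tangent direction
    (cross(contact_normal, tangent_loi)).
    """

    loi_dir: np.ndarray
    tangent_loi: np.ndarray
    tangent_perp: np.ndarray


def _sunflower_disc(n: int, radius: float) -> np.ndarray:
    """Deterministic uniform-density layout of n points on a disc."""
    k = np.arange(1, n + 1)
    r = radius * np.sqrt((k - 0.5) / n)
    th = k * np.pi * (3.0 - np.sqrt(5.0))
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)


def _symmetric_disc(n: int, radius: float) -> np.ndarray:
    """Disc layout symmetric under point reflection (u, v) -> (-u, -v).

    The symmetry makes the discretized figure-8 field exactly odd under a
    180-degree pose rotation, so mirror-partner magnitudes agree to
    round-off rather than to discretization error.
    """
    pts = []
    if n % 2 == 1:
        pts.append(np.zeros((1, 2)))
    half = _sunflower_disc(n // 2, radius)
    if len(half):
        pts.extend([half, -half])
    return np.vstack(pts)


def coil_dipoles(coil: CoilModel, pose: CoilPose,
                 standoff: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Discretize the coil as magnetic dipoles for the spherical solver.

    Wing centers sit at +/- wing_separation/2 along the wing axis
    cross(contact_normal, handle_dir) — perpendicular to the handle, as in
    physical figure-8 coils, so the junction current and the slowly
    decaying direction of the field run along the handle.  Each wing's
    total moment turns_per_wing * pi * wing_radius^2 (per unit slew rate)
    is split over ``dipoles_per_wing`` dipoles in the coil plane, directed
    along the contact normal with the wing's winding sign.

    Returns (positions_mm, moments_m2): moments are in m^2 (multiply by
    di/dt in A/s for the physical moment rate).
    """
    n_hat = pose.contact_normal
    handle = pose.handle_dir
    wing_axis = np.cross(n_hat, handle)
    wing_axis = wing_axis / np.linalg.norm(wing_axis)
    origin = pose.center + standoff * n_hat

    area_m2 = np.pi * (coil.wing_radius * 1e-3) ** 2
    per_dipole = coil.turns_per_wing * area_m2 / coil.dipoles_per_wing
    disc = _symmetric_disc(coil.dipoles_per_wing, coil.wing_radius)

    positions, moments = [], []
    for sense, side in zip(coil.winding_sense, (+1.0, -1.0)):
        wing_center = origin + side * (coil.wing_separation / 2.0) * wing_axis
        for u, v in disc:
            positions.append(wing_center + u * wing_axis + v * handle)
            moments.append(sense * per_dipole * n_hat)
    return np.asarray(positions), np.asarray(moments)


def initial_pose(scalp_point: np.ndarray, scalp_normal: np.ndarray,
                 midsagittal_normal: np.ndarray = (1.0, 0.0, 0.0)) -> CoilPose:
    """Initial clinical orientation: handle posterolateral, 45 deg to mid-sagittal.

    The handle is the tangent-plane vector whose horizontal projection
    makes a 45-degree angle with the mid-sagittal plane, signed into the
    posterolateral (-y, -x) half-plane for left-hemisphere sites.  The
    construction assumes the RAS-like frame (x right, y anterior,
    z superior) with mid-sagittal plane x = 0.

    Raises DegenerateFrameError when the scalp normal is horizontal
    (including normals parallel to the mid-sagittal normal), where no
    tangent vector with the required horizontal direction exists.
    """
    n = np.asarray(scalp_normal, float)
    n = n / np.linalg.norm(n)
    m = np.asarray(midsagittal_normal, float)
    m = m / np.linalg.norm(m)
    z_hat = np.array([0.0, 0.0, 1.0])
    if abs(n @ z_hat) < 1e-9:
        raise DegenerateFrameError("scalp normal is horizontal; 45-degree "
                                   "posterolateral handle undefined")
    # posterolateral horizontal direction at 45 deg to the plane x=0
    lateral = -m if m[0] >= 0 else m            # toward -x (left)
    d45 = (lateral + np.array([0.0, -1.0, 0.0])) / np.sqrt(2.0)
    handle = d45 - ((d45 @ n) / (z_hat @ n)) * z_hat
    return CoilPose(center=np.asarray(scalp_point, float), contact_normal=n,
                    handle_dir=handle / np.linalg.norm(handle), rotation_deg=0.0)


def rotate_pose(pose: CoilPose, angle_deg: float,
                intracranial_target: np.ndarray) -> CoilPose:
    """Rotate the coil about the axis from its center to the target.

    Counterclockwise is the right-hand sense about the inward axis
    (looking along the axis from the coil toward the target).  The handle
    is re-orthogonalized against the (rotated) contact normal, and
    ``rotation_deg`` accumulates modulo (-180, 180].
    """
    target = np.asarray(intracranial_target, float)
    axis = target - pose.center
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("rotation axis undefined: target equals coil center")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm)
    normal = rot.apply(pose.contact_normal)
    handle = rot.apply(pose.handle_dir)
    return CoilPose(center=pose.center.copy(), contact_normal=normal,
                    handle_dir=handle,
                    rotation_deg=_wrap_angle(pose.rotation_deg + angle_deg))


def build_sweep(pose: CoilPose, target: np.ndarray) -> OrientationSweep:
    """Explicit poses at 0, 30, ..., 150 degrees plus mirror bookkeeping.

    Angles -180..-30 are not instantiated: each maps to its explicit
    partner (angle + 180), whose field magnitudes it shares exactly by the
    figure-8 antisymmetry.
    """
    poses = [rotate_pose(pose, a, target) for a in SWEEP_ANGLES_DEG]
    partners = {a - 180.0: a for a in SWEEP_ANGLES_DEG}
    return OrientationSweep(base_pose=pose, angles_deg=SWEEP_ANGLES_DEG,
                            poses=poses, mirror_partner=partners)


def loi_orientations(functional_point: np.ndarray, anatomical_point: np.ndarray,
                     pose: CoilPose) -> tuple[CoilPose, CoilPose, LoiFrame]:
    """Handle-parallel and handle-perpendicular orientations w.r.t. the LOI.

    The line of interest runs from the anatomical to the functional
    cortical target; the coil is assumed positioned at the functional
    target's scalp entry.  The parallel pose aligns the handle with the
    tangent-plane projection of the LOI, the perpendicular pose with
    cross(contact_normal, tangent_loi) — the figure-8 symmetry makes the
    two possible signs of that vector field-equivalent.
    """
    f = np.asarray(functional_point, float)
    a = np.asarray(anatomical_point, float)
    loi = f - a
    norm = np.linalg.norm(loi)
    if norm < 1e-12:
        raise DegenerateLoiError("functional and anatomical targets coincide")
    loi_dir = loi / norm
    n = pose.contact_normal
    t = loi_dir - (loi_dir @ n) * n
    tnorm = np.linalg.norm(t)
    if tnorm < 1e-8:
        raise DegenerateLoiError("LOI parallel to the contact normal")
    tangent_loi = t / tnorm
    tangent_perp = np.cross(n, tangent_loi)
    tangent_perp = tangent_perp / np.linalg.norm(tangent_perp)

    def _angle_from_base(h):
        s = np.cross(pose.handle_dir, h) @ n
        c = pose.handle_dir @ h
        return _wrap_angle(np.rad2deg(np.arctan2(s, c)) + pose.rotation_deg)

    parallel = CoilPose(pose.center.copy(), n.copy(), tangent_loi,
                        rotation_deg=_angle_from_base(tangent_loi))
    perpendicular = CoilPose(pose.center.copy(), n.copy(), tangent_perp,
                             rotation_deg=_angle_from_base(tangent_perp))
    return parallel, perpendicular, LoiFrame(loi_dir, tangent_loi, tangent_perp)
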
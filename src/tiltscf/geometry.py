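"""Euler-angle conventions, rotation construction, and viewing directions.

All public interfaces take and return angles in **degrees**; radians are used
only internally.  The Euler convention is intrinsic ZYZ ``(rot, tilt, psi)``:
the rotation matrix is ``Rz(rot) @ Ry(tilt) @ Rz(psi)``, matching the RELION
STAR-file convention (``_rlnAngleRot``, ``_rlnAngleTilt``, ``_rlnAnglePsi``).

The viewing (projection) direction of a triplet is the unit vector

    d = (sin(tilt) cos(rot), sin(tilt) sin(rot), cos(tilt)),

i.e. the image of the beam axis ``z`` under the triplet's rotation matrix;
it is independent of the in-plane angle ``psi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EulerTriplet",
    "OrientationSet",
    "euler_to_rotation",
    "rotations_from_eulers",
    "rotation_to_euler",
    "eulers_from_rotations",
    "viewing_direction",
    "viewing_directions",
    "normalize_angles",
    "rotation_about_axis",
]


@dataclass(frozen=True)
class EulerTriplet:
    """One (rot, tilt, psi) orientation in degrees, intrinsic ZYZ."""

    rot: float
    tilt: float
    psi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rot, self.tilt, self.psi], dtype=float)


def _check_finite(angles: np.ndarray) -> None:
    if not np.all(np.isfinite(angles)):
        raise ValueError("Euler angles must be finite")


def rotations_from_eulers(angles: np.ndarray) -> np.ndarray:
    """Rotation matrices for an (N, 3) array of (rot, tilt, psi) in degrees.

    Returns an (N, 3, 3) array of proper orthonormal matrices
    ``Rz(rot) @ Ry(tilt) @ Rz(psi)``.
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    _check_finite(angles)
    rot, tilt, psi = np.deg2rad(angles.T)
    cr, sr = np.cos(rot), np.sin(rot)
    ct, st = np.cos(tilt), np.sin(tilt)
    cp, sp = np.cos(psi), np.sin(psi)
    R = np.empty(angles.shape[:1] + (3, 3))
    R[:, 0, 0] = cr * ct * cp - sr * sp
    R[:, 0, 1] = -cr * ct * sp - sr * cp
    R[:, 0, 2] = cr * st
    R[:, 1, 0] = sr * ct * cp + cr * sp
    R[:, 1, 1] = -sr * ct * sp + cr * cp
    R[:, 1, 2] = sr * st
    R[:, 2, 0] = -st * cp
    R[:, 2, 1] = st * sp
    R[:, 2, 2] = ct
    return R


def euler_to_rotation(t: EulerTriplet | tuple[float, float, float]) -> np.ndarray:
    """3x3 proper rotation matrix of a single Euler triplet (degrees)."""
    if isinstance(t, EulerTriplet):
        arr = t.as_array()
    else:
        arr = np.asarray(t, dtype=float)
    return rotations_from_eulers(arr[None, :])[0]


def eulers_from_rotations(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rotations_from_eulers`: (N, 3, 3) -> (N, 3) degrees.

    Canonical ranges: tilt in [0, 180], rot and psi in (-180, 180].  At the
    gimbal-lock poles (tilt = 0 or 180) rot is set to 0 and the full in-plane
    rotation is carried by psi.
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    if single:
        R = R[None]
    # atan2 form is well-conditioned near the poles, unlike arccos(R22)
    st = np.hypot(R[:, 0, 2], R[:, 1, 2])
    tilt = np.arctan2(st, R[:, 2, 2])
    st_ok = st > 1e-9
    rot = np.where(st_ok, np.arctan2(R[:, 1, 2], R[:, 0, 2]), 0.0)
    psi = np.where(st_ok, np.arctan2(R[:, 2, 1], -R[:, 2, 0]), 0.0)
    # gimbal lock: R reduces to Rz(rot+psi) (or Ry(180) Rz(psi-rot));
    # attribute the whole in-plane rotation to psi, with rot = 0
    locked = ~st_ok
    if np.any(locked):
        psi = psi.copy()
        psi[locked] = np.arctan2(R[locked, 1, 0], R[locked, 1, 1])
    out = np.stack([np.rad2deg(rot), np.rad2deg(tilt), np.rad2deg(psi)], axis=1)
    return out[0] if single else out


def rotation_to_euler(R: np.ndarray) -> EulerTriplet:
    rot, tilt, psi = eulers_from_rotations(R)
    return EulerTriplet(float(rot), float(tilt), float(psi))


def viewing_directions(angles: np.ndarray) -> np.ndarray:
    """Unit viewing directions, (N, 3), for (N, 3) Euler angles in degrees."""
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    _check_finite(angles)
    rot = np.deg2rad(angles[:, 0])
    tilt = np.deg2rad(angles[:, 1])
    st = np.sin(tilt)
    return np.stack([st * np.cos(rot), st * np.sin(rot), np.cos(tilt)], axis=1)


def viewing_direction(t: EulerTriplet | tuple[float, float, float]) -> np.ndarray:
    if isinstance(t, EulerTriplet):
        arr = t.as_array()
    else:
        arr = np.asarray(t, dtype=float)
    return viewing_directions(arr[None, :])[0]


def normalize_angles(t: EulerTriplet | tuple[float, float, float]) -> EulerTriplet:
    """Canonicalize a triplet to tilt in [0, 180], rot/psi in (-180, 180].

    The returned triplet represents the same rotation matrix (round-trip
    through the matrix form), so ``normalize(normalize(x)) == normalize(x)``.
    """
    return rotation_to_euler(euler_to_rotation(t))


def rotation_about_axis(axis: str | np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about a named lab axis or unit vector."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if isinstance(axis, str):
        axis = axis.lower()
        if axis == "x":
            return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
        if axis == "y":
            return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
        if axis == "z":
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
        raise ValueError(f"unknown axis label {axis!r}")
    v = np.asarray(axis, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("axis vector must be nonzero")
    x, y, z = v / n
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


@dataclass
class OrientationSet:
    """Ordered collection of Euler triplets with optional per-item weights.

    ``angles`` is an (N, 3) float array of (rot, tilt, psi) in degrees.
    Weights default to 1 and must be nonnegative with positive sum.
    """

    angles: np.ndarray
    weights: np.ndarray | None = None
    label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise ValueError(f"angles must be (N, 3), got {self.angles.shape}")
        _check_finite(self.angles)
        if self.weights is None:
            self.weights = np.ones(len(self.angles))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.angles),):
                raise ValueError("weights must match number of orientations")
            if np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative")
            if len(self.weights) and self.weights.sum() <= 0:
                raise ValueError("sum of weights must be positive")

    def __len__(self) -> int:
        return len(self.angles)

    def rotations(self) -> np.ndarray:
        return rotations_from_eulers(self.angles)

    def directions(self) -> np.ndarray:
        return viewing_directions(self.angles)

    def normalized(self) -> "OrientationSet":
        angles = eulers_from_rotations(rotations_from_eulers(self.angles))
        return OrientationSet(angles, self.weights.copy(), self.label, self.seed)

    def __getitem__(self, i: int) -> EulerTriplet:
        return EulerTriplet(*self.angles[i])
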
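"""Low-level vector geometry: torsions, NeRF atom placement, rigid fits.

All angles at this layer are in degrees (the unit used throughout the
package); positions are Angstrom numpy arrays of shape (3,).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

# Ideal backbone geometry used for rebuilds, fixtures and virtual cutpoint
# atoms.  The peptide C-N bond of 1.329 A is the reference value the loop
# analyzer flags deviations against.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

#: ideal CA_i .. N_{i+1} distance implied by the constants above
IDEAL_CA_N_NEXT = float(
    np.sqrt(
        BOND_CA_C**2
        + BOND_C_N**2
        - 2.0 * BOND_CA_C * BOND_C_N * np.cos(np.deg2rad(ANGLE_CA_C_N))
    )
)
#: ideal C_i .. CA_{i+1} distance
IDEAL_C_CA_NEXT = float(
    np.sqrt(
        BOND_C_N**2
        + BOND_N_CA**2
        - 2.0 * BOND_C_N * BOND_N_CA * np.cos(np.deg2rad(ANGLE_C_N_CA))
    )
)


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = normalize(np.asarray(a) - np.asarray(b))
    v = normalize(np.asarray(c) - np.asarray(b))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    # scalar arithmetic: this sits on the kinematics hot path
    b0x = p0[0] - p1[0]; b0y = p0[1] - p1[1]; b0z = p0[2] - p1[2]
    b1x = p2[0] - p1[0]; b1y = p2[1] - p1[1]; b1z = p2[2] - p1[2]
    b2x = p3[0] - p2[0]; b2y = p3[1] - p2[1]; b2z = p3[2] - p2[2]
    n = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    if n == 0.0:
        raise ValueError("zero-length bond in dihedral")
    b1x /= n; b1y /= n; b1z /= n
    d0 = b0x * b1x + b0y * b1y + b0z * b1z
    vx = b0x - d0 * b1x; vy = b0y - d0 * b1y; vz = b0z - d0 * b1z
    d2 = b2x * b1x + b2y * b1y + b2z * b1z
    wx = b2x - d2 * b1x; wy = b2y - d2 * b1y; wz = b2z - d2 * b1z
    x = vx * wx + vy * wy + vz * wz
    cx = b1y * vz - b1z * vy
    cy = b1z * vx - b1x * vz
    cz = b1x * vy - b1y * vx
    y = cx * wx + cy * wy + cz * wz
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return float(a)


def place_atom(a, b, c, bond_length: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d such that |c-d| = bond_length,
    angle(b, c, d) = ``angle`` and dihedral(a, b, c, d) = ``torsion``
    (both in degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = normalize(c - b)
    ab = b - a
    n = normalize(np.array([ab[1] * bc[2] - ab[2] * bc[1],
                            ab[2] * bc[0] - ab[0] * bc[2],
                            ab[0] * bc[1] - ab[1] * bc[0]]))
    m = np.array([n[1] * bc[2] - n[2] * bc[1],
                  n[2] * bc[0] - n[0] * bc[2],
                  n[0] * bc[1] - n[1] * bc[0]])
    d_local = bond_length * np.array(
        [
            -np.cos(ang),
            np.sin(ang) * np.cos(tor),
            np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(origin, axis, angle_deg: float):
    """Return (R, t) implementing rotation by ``angle_deg`` about the axis
    through ``origin`` with direction ``axis``: x -> R @ x + t."""
    origin = np.asarray(origin, dtype=float)
    axis = normalize(np.asarray(axis, dtype=float))
    theta = np.deg2rad(angle_deg)
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)
    t = origin - R @ origin
    return R, t


def kabsch(reference: np.ndarray, mobile: np.ndarray):
    """Least-squares rigid transform (R, t) mapping ``mobile`` onto
    ``reference``: reference ~= mobile @ R.T + t.

    Both arrays are (n, 3) with n >= 3 paired points.
    """
    reference = np.asarray(reference, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    ref_c = reference.mean(axis=0)
    mob_c = mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    return R, t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(reference: np.ndarray, mobile: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of ``mobile`` on ``reference``."""
    R, t = kabsch(reference, mobile)
    moved = mobile @ R.T + t
    return rmsd(reference, moved)
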
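"""Low-level vector geometry: dihedrals, internal-to-Cartesian placement, superposition.

All angles are in degrees on the wire; radians are used only transiently.
Coordinates are float64 numpy arrays of shape (3,) or (n, 3), in Angstroms.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def wrap_angle(a):
    """Wrap angle(s) in degrees to the half-open interval (-180, 180]."""
    w = (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    if np.ndim(a) == 0:
        return float(w)
    return w


def _vec_angle_scalar(ux, uy, uz, vx, vy, vz):
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    if nu == 0.0 or nv == 0.0:
        return float("nan")
    cos = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    cos = max(-1.0, min(1.0, cos))
    return math.degrees(math.acos(cos))


def bond_angle(a, b, c):
    """Angle a-b-c at vertex b, in degrees in [0, 180]."""
    return _vec_angle_scalar(
        a[0] - b[0], a[1] - b[1], a[2] - b[2],
        c[0] - b[0], c[1] - b[1], c[2] - b[2],
    )


def dihedral(p0, p1, p2, p3):
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention, in (-180, 180].

    Returns NaN when any three consecutive atoms are collinear (undefined plane).
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return float("nan")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def dihedral_batch(p0, p1, p2, p3):
    """Vectorized :func:`dihedral` over (n, 3) coordinate arrays."""
    b0 = np.asarray(p1, float) - p0
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    out = wrap_angle(np.degrees(np.arctan2(y, x)))
    out = np.where((norm1 < 1e-9) | (norm2 < 1e-9), np.nan, out)
    return out


def vec_angle(u, v):
    """Angle between two vectors in degrees in [0, 180]."""
    return _vec_angle_scalar(u[0], u[1], u[2], v[0], v[1], v[2])


def place_atom(a, b, c, bond: float, angle: float, torsion: float):
    """Place atom D from internal coordinates (NeRF construction).

    D is bonded to `c` at distance `bond`, with bond angle b-c-D = `angle`
    (degrees) and dihedral a-b-c-D = `torsion` (degrees).
    """
    # scalar math (not numpy) on purpose: this sits in the per-move hot loop
    ax, ay, az = float(a[0]), float(a[1]), float(a[2])
    bx, by, bz = float(b[0]), float(b[1]), float(b[2])
    cx, cy, cz = float(c[0]), float(c[1]), float(c[2])
    ang = math.radians(angle)
    tor = math.radians(torsion)
    dx = -bond * math.cos(ang)
    dy = bond * math.sin(ang) * math.cos(tor)
    dz = -bond * math.sin(ang) * math.sin(tor)
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    return np.array(
        [
            cx + bcx * dx + mx * dy + nx * dz,
            cy + bcy * dx + my * dy + ny * dz,
            cz + bcz * dx + mz * dy + nz * dz,
        ]
    )


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns (transformed mobile coordinates, rmsd over the fitted atoms).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if weights is None:
        weights = np.ones(len(mobile))
    w = np.asarray(weights, float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc, weights=w)
    moved = rot.apply(mobile - mc) + rc
    d2 = ((moved - reference) ** 2).sum(axis=1)
    return moved, float(np.sqrt((w * d2).sum()))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Cα-style RMSD after optimal superposition of equal-length coordinate sets."""
    moved, r = kabsch_superpose(a, b)
    return r


def transform_of(mobile: np.ndarray, reference: np.ndarray):
    """Return (rotation matrix, translation) minimizing RMSD of mobile onto reference."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    return R, t
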
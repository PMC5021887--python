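"""Low-level backbone geometry: torsion angles, internal-coordinate atom
placement (NeRF) and Kabsch superposition.

All angles are in degrees, wrapped to (-180, 180]. Coordinates are in Å.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "dihedral",
    "place_atom",
    "kabsch_rmsd_coords",
    "kabsch_rotation",
]


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    wrapped = -np.remainder(-np.asarray(theta, dtype=float) + 180.0, 360.0) + 180.0
    return wrapped


def dihedral(p0, p1, p2, p3):
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention.

    Accepts single points of shape (3,) or stacked points of shape (k, 3);
    returns a scalar or an array of k angles in (-180, 180].
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float):
    """Place atom D given three predecessors so that |C-D| = bond_length,
    angle(B,C,D) = bond_angle and torsion(A,B,C,D) = torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(bond_angle)
    tor = np.radians(torsion)
    d = bond_length * (
        -np.cos(ang) * bc + np.sin(ang) * (np.cos(tor) * m - np.sin(tor) * n)
    )
    return c + d


def kabsch_rmsd_coords(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Least-squares RMSD between point sets after optimal rigid-body
    superposition (translation + proper rotation).

    p, q: arrays of shape (..., L, 3); leading axes broadcast as a batch.
    The residual is evaluated on the explicitly rotated coordinates, which
    is numerically exact near zero (unlike the E0 - 2Σσ shortcut).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p - p.mean(axis=-2, keepdims=True)
    q = q - q.mean(axis=-2, keepdims=True)
    shape = np.broadcast_shapes(p.shape, q.shape)
    p, q = np.broadcast_to(p, shape), np.broadcast_to(q, shape)
    r = kabsch_rotation(p, q)
    resid = p @ r - q
    return np.sqrt(np.sum(resid * resid, axis=(-2, -1)) / shape[-2])


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R minimising ||p @ R - q|| for centered p, q
    of shape (L, 3) (or batched (..., L, 3))."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    h = np.swapaxes(p, -2, -1) @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if np.ndim(d) == 0:
        u = u.copy()
        u[:, -1] *= d
    else:
        u = u.copy()
        u[..., :, -1] *= d[..., None]
    return u @ vt
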
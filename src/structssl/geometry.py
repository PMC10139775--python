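"""Backbone torsion geometry: signed dihedrals and internal-coordinate
atom placement (the NeRF construction used to grow synthetic chains)."""
from __future__ import annotations

import numpy as np


class UndefinedDihedralError(ValueError):
    """Raised when a torsion is geometrically undefined (collinear atoms)."""


def dihedral(p0, p1, p2, p3, *, eps: float = 1e-12) -> float:
    """Signed torsion angle of the four points, IUPAC convention.

    trans (antiperiplanar) = pi, eclipsed (synperiplanar) = 0; the sign
    follows the right-hand rule about the p1 -> p2 axis.  Returns a value
    in (-pi, pi].
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < eps or np.linalg.norm(n1) < eps or np.linalg.norm(n2) < eps:
        raise UndefinedDihedralError("collinear or coincident points")
    m1 = np.cross(n1, b2 / nb2)
    x = float(n1 @ n2)
    y = float(-(m1 @ n2))
    angle = float(np.arctan2(y, x))
    if angle <= -np.pi:
        angle = np.pi
    return angle


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom d so that |c-d| = bond_length, angle(b,c,d) = bond_angle
    and dihedral(a,b,c,d) = torsion."""
    a, b, c = (np.asarray(p, dtype=np.float64) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond_length * np.array(
        [
            -np.cos(bond_angle),
            np.sin(bond_angle) * np.cos(torsion),
            np.sin(bond_angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def apply_rigid_motion(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply x -> R x + t row-wise."""
    return coords @ np.asarray(rotation).T + np.asarray(translation)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
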
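"""Low-level vector geometry: dihedrals, internal-coordinate atom placement,
and rigid transforms. Everything operates on float64 numpy arrays in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "bond_angle", "place_atom", "apply_transform"]


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    b1 = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    b2 = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    b3 = np.asarray(d, dtype=float) - np.asarray(c, dtype=float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms a, b, c.

    D is at distance ``bond`` from c, with angle b-c-D equal to ``angle``
    (degrees) and dihedral a-b-c-D equal to ``torsion`` (degrees). This is the
    natural-extension-reference-frame construction used by backbone builders.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle)
    tor = np.radians(torsion)

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)

    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    """Apply x -> R x + t to an (n, 3) coordinate array."""
    return np.asarray(coords, float) @ np.asarray(rotation, float).T + np.asarray(translation, float)
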
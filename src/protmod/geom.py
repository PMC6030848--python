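"""Low-level vector geometry for peptide construction and analysis.

All coordinates are in Ångström, angles in degrees unless noted. The
internal-coordinate atom placement (`place_atom`) follows the standard
NeRF construction: an atom D is positioned from three predecessors
A-B-C given the bond length C-D, the bond angle B-C-D and the torsion
A-B-C-D.
"""

from __future__ import annotations

import numpy as np

# Ideal peptide-backbone internal coordinates (Engh & Huber style averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5
OMEGA_TRANS = 180.0

# Heavy-atom van der Waals radii by element.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def norm(v: np.ndarray) -> float:
    return float(np.linalg.norm(v))


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u = unit(np.asarray(a) - np.asarray(b))
    v = unit(np.asarray(c) - np.asarray(b))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion angle a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    bond_angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D from predecessors A, B, C and internal coordinates.

    `bond` is |C-D|, `bond_angle` is the B-C-D angle and `torsion` the
    A-B-C-D dihedral, both in degrees.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.radians(bond_angle)
    chi = -np.radians(torsion)  # so that dihedral(a, b, c, placed) == torsion
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ]
    )
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of `mobile` onto `target`.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best matches `target`, with a
    proper rotation (det = +1) enforced.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (n, 3) arrays")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_no_fit(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
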
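"""Side-chain construction from internal coordinates.

Each residue type carries a small z-matrix: every side-chain atom beyond
CB is placed from three reference atoms with a bond length, bond angle
and a torsion that is either one of the chi dihedrals (possibly with a
branch offset) or a fixed value (ring atoms). Values are canonical
averages; at this resolution only connectivity and approximate sterics
matter.
"""

from __future__ import annotations

import numpy as np

from .geom import place_atom

# torsion spec: ("chi", k, offset_degrees) or ("fixed", value_degrees)
# entry: (atom, ref_a, ref_b, ref_c, bond, angle, torsion_spec)
SIDECHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [
        ("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi", 1, 0.0)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "VAL": [
        ("CG1", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 122.0)),
    ],
    "LEU": [
        ("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 122.0)),
    ],
    "ILE": [
        ("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -122.0)),
        ("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "MET": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "ASP": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "ASN": [
        ("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "GLU": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "GLN": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "LYS": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", "CB", "CG", "CD", 1.508, 111.3, ("chi", 3, 0.0)),
        ("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi", 4, 0.0)),
    ],
    "ARG": [
        ("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", "CB", "CG", "CD", 1.460, 112.0, ("chi", 3, 0.0)),
        ("CZ", "CG", "CD", "NE", 1.330, 124.2, ("chi", 4, 0.0)),
        ("NH1", "CD", "NE", "CZ", 1.326, 120.0, ("fixed", 0.0)),
        ("NH2", "CD", "NE", "CZ", 1.326, 120.0, ("fixed", 180.0)),
    ],
    "PHE": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.382, 120.7, ("fixed", 180.0)),
        ("CE2", "CB", "CG", "CD2", 1.382, 120.7, ("fixed", 180.0)),
        ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, ("fixed", 0.0)),
    ],
    "TYR": [
        ("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 180.0)),
        ("CE1", "CB", "CG", "CD1", 1.382, 120.7, ("fixed", 180.0)),
        ("CE2", "CB", "CG", "CD2", 1.382, 120.7, ("fixed", 180.0)),
        ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, ("fixed", 0.0)),
        ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, ("fixed", 180.0)),
    ],
    "TRP": [
        ("CG", "N", "CA", "CB", 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.433, 126.7, ("chi", 2, 180.0)),
        ("NE1", "CB", "CG", "CD1", 1.374, 110.2, ("fixed", 180.0)),
        ("CE2", "CB", "CG", "CD2", 1.409, 107.2, ("fixed", 180.0)),
        ("CE3", "CB", "CG", "CD2", 1.398, 133.9, ("fixed", 0.0)),
        ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, ("fixed", 180.0)),
        ("CZ3", "CG", "CD2", "CE3", 1.382, 118.6, ("fixed", 180.0)),
        ("CH2", "CE3", "CZ3", "CZ2", 1.368, 117.5, ("fixed", 0.0)),
    ],
    "HIS": [
        ("CG", "N", "CA", "CB", 1.497, 113.7, ("chi", 1, 0.0)),
        ("ND1", "CA", "CB", "CG", 1.371, 122.8, ("chi", 2, 0.0)),
        ("CD2", "CA", "CB", "CG", 1.356, 131.0, ("chi", 2, 180.0)),
        ("CE1", "CB", "CG", "ND1", 1.319, 109.0, ("fixed", 180.0)),
        ("NE2", "CB", "CG", "CD2", 1.374, 107.1, ("fixed", 180.0)),
    ],
    # proline's ring is built with a fixed approximate pucker
    "PRO": [
        ("CG", "N", "CA", "CB", 1.492, 104.5, ("fixed", 30.0)),
        ("CD", "CA", "CB", "CG", 1.503, 106.1, ("fixed", -35.0)),
    ],
}

CHI_COUNTS = {
    "ALA": 0, "GLY": 0, "PRO": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "LEU": 2, "ILE": 2, "ASP": 2, "ASN": 2, "PHE": 2, "TYR": 2,
    "TRP": 2, "HIS": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}


def element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def build_side_chain(
    backbone: dict[str, np.ndarray], res_name: str, chis: tuple[float, ...]
) -> dict[str, np.ndarray]:
    """Place side-chain atoms beyond CB for `res_name` at the given chis.

    `backbone` must contain N, CA, CB (CB not needed for GLY). Returns
    atom name -> coordinate for the newly placed atoms.
    """
    if res_name not in SIDECHAIN_TOPOLOGY:
        raise KeyError(f"no side-chain topology for {res_name}")
    coords = dict(backbone)
    placed: dict[str, np.ndarray] = {}
    for atom, a, b, c, bond, ang, tors in SIDECHAIN_TOPOLOGY[res_name]:
        if tors[0] == "chi":
            _, k, offset = tors
            if k > len(chis):
                raise ValueError(f"{res_name} atom {atom} needs chi{k}, got {len(chis)}")
            torsion = chis[k - 1] + offset
        else:
            torsion = tors[1]
        pos = place_atom(coords[a], coords[b], coords[c], bond, ang, torsion)
        coords[atom] = pos
        placed[atom] = pos
    return placed
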
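"""Side-chain heavy-atom templates from chi angles and idealized internal
coordinates.

Each amino acid's side chain is described as a small topology table of
(atom, parent, angle-reference, torsion-reference, bond length, bond angle,
torsion), where the torsion is either a fixed value (ring and planar-group
atoms) or one of the chi angles plus an offset (branch atoms). Atoms are placed
sequentially with the natural-extension-reference-frame construction, starting
from the residue's own N/CA/C backbone frame. Bond lengths and angles are
Engh-Huber-style idealized averages; ring geometry is approximated as planar.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom

# CB placement shared by all non-glycine residues:
# bonded to CA, angle N-CA-CB, dihedral C-N-CA-CB = -122.6 deg (L-configuration).
_CB = ("CB", "CA", "N", "C", 1.530, 110.5, -122.6)

Chi = tuple  # ("chi", k, offset_deg)


def _chi(k: int, offset: float = 0.0) -> Chi:
    return ("chi", k, offset)


# fmt: off
SIDECHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "G": [],
    "A": [_CB],
    "S": [_CB, ("OG",  "CB", "CA", "N", 1.417, 110.8, _chi(1))],
    "C": [_CB, ("SG",  "CB", "CA", "N", 1.808, 114.4, _chi(1))],
    "T": [_CB, ("OG1", "CB", "CA", "N", 1.433, 109.6, _chi(1)),
               ("CG2", "CB", "CA", "N", 1.521, 110.5, _chi(1, -122.0))],
    "V": [_CB, ("CG1", "CB", "CA", "N", 1.527, 110.5, _chi(1)),
               ("CG2", "CB", "CA", "N", 1.527, 110.5, _chi(1, 122.0))],
    "L": [_CB, ("CG",  "CB", "CA", "N", 1.530, 116.3, _chi(1)),
               ("CD1", "CG", "CB", "CA", 1.521, 110.7, _chi(2)),
               ("CD2", "CG", "CB", "CA", 1.521, 110.7, _chi(2, 122.0))],
    "I": [_CB, ("CG1", "CB", "CA", "N", 1.530, 110.4, _chi(1)),
               ("CG2", "CB", "CA", "N", 1.521, 110.5, _chi(1, -122.0)),
               ("CD1", "CG1", "CB", "CA", 1.513, 113.8, _chi(2))],
    "M": [_CB, ("CG",  "CB", "CA", "N", 1.520, 114.1, _chi(1)),
               ("SD",  "CG", "CB", "CA", 1.803, 112.7, _chi(2)),
               ("CE",  "SD", "CG", "CB", 1.791, 100.9, _chi(3))],
    "P": [_CB, ("CG",  "CB", "CA", "N", 1.492, 104.5, _chi(1)),
               ("CD",  "CG", "CB", "CA", 1.503, 106.1, _chi(2))],
    "F": [_CB, ("CG",  "CB", "CA", "N", 1.502, 113.8, _chi(1)),
               ("CD1", "CG", "CB", "CA", 1.390, 120.8, _chi(2)),
               ("CD2", "CG", "CB", "CA", 1.390, 120.8, _chi(2, 180.0)),
               ("CE1", "CD1", "CG", "CB", 1.390, 120.0, 180.0),
               ("CE2", "CD2", "CG", "CB", 1.390, 120.0, 180.0),
               ("CZ",  "CE1", "CD1", "CG", 1.390, 120.0, 0.0)],
    "Y": [_CB, ("CG",  "CB", "CA", "N", 1.502, 113.8, _chi(1)),
               ("CD1", "CG", "CB", "CA", 1.390, 120.8, _chi(2)),
               ("CD2", "CG", "CB", "CA", 1.390, 120.8, _chi(2, 180.0)),
               ("CE1", "CD1", "CG", "CB", 1.390, 120.0, 180.0),
               ("CE2", "CD2", "CG", "CB", 1.390, 120.0, 180.0),
               ("CZ",  "CE1", "CD1", "CG", 1.390, 120.0, 0.0),
               ("OH",  "CZ", "CE1", "CD1", 1.380, 120.0, 180.0)],
    "W": [_CB, ("CG",  "CB", "CA", "N", 1.498, 113.6, _chi(1)),
               ("CD1", "CG", "CB", "CA", 1.370, 126.9, _chi(2)),
               ("CD2", "CG", "CB", "CA", 1.433, 126.7, _chi(2, 180.0)),
               ("NE1", "CD1", "CG", "CB", 1.380, 110.2, 180.0),
               ("CE2", "CD2", "CG", "CB", 1.410, 107.2, 180.0),
               ("CE3", "CD2", "CG", "CB", 1.400, 133.9, 0.0),
               ("CZ2", "CE2", "CD2", "CG", 1.400, 122.4, 180.0),
               ("CZ3", "CE3", "CD2", "CG", 1.390, 118.8, 180.0),
               ("CH2", "CZ2", "CE2", "CD2", 1.370, 117.5, 0.0)],
    "D": [_CB, ("CG",  "CB", "CA", "N", 1.516, 113.0, _chi(1)),
               ("OD1", "CG", "CB", "CA", 1.249, 118.5, _chi(2)),
               ("OD2", "CG", "CB", "CA", 1.249, 118.5, _chi(2, 180.0))],
    "N": [_CB, ("CG",  "CB", "CA", "N", 1.516, 112.6, _chi(1)),
               ("OD1", "CG", "CB", "CA", 1.231, 120.8, _chi(2)),
               ("ND2", "CG", "CB", "CA", 1.328, 116.4, _chi(2, 180.0))],
    "E": [_CB, ("CG",  "CB", "CA", "N", 1.530, 114.1, _chi(1)),
               ("CD",  "CG", "CB", "CA", 1.516, 114.0, _chi(2)),
               ("OE1", "CD", "CG", "CB", 1.249, 118.5, _chi(3)),
               ("OE2", "CD", "CG", "CB", 1.249, 118.5, _chi(3, 180.0))],
    "Q": [_CB, ("CG",  "CB", "CA", "N", 1.530, 114.1, _chi(1)),
               ("CD",  "CG", "CB", "CA", 1.516, 112.6, _chi(2)),
               ("OE1", "CD", "CG", "CB", 1.231, 120.8, _chi(3)),
               ("NE2", "CD", "CG", "CB", 1.328, 116.4, _chi(3, 180.0))],
    "K": [_CB, ("CG",  "CB", "CA", "N", 1.520, 114.1, _chi(1)),
               ("CD",  "CG", "CB", "CA", 1.520, 111.3, _chi(2)),
               ("CE",  "CD", "CG", "CB", 1.520, 111.3, _chi(3)),
               ("NZ",  "CE", "CD", "CG", 1.489, 111.9, _chi(4))],
    "R": [_CB, ("CG",  "CB", "CA", "N", 1.520, 114.1, _chi(1)),
               ("CD",  "CG", "CB", "CA", 1.520, 111.3, _chi(2)),
               ("NE",  "CD", "CG", "CB", 1.460, 112.0, _chi(3)),
               ("CZ",  "NE", "CD", "CG", 1.330, 124.2, _chi(4)),
               ("NH1", "CZ", "NE", "CD", 1.330, 120.0, 180.0),
               ("NH2", "CZ", "NE", "CD", 1.330, 120.0, 0.0)],
    "H": [_CB, ("CG",  "CB", "CA", "N", 1.492, 113.8, _chi(1)),
               ("ND1", "CG", "CB", "CA", 1.380, 122.7, _chi(2)),
               ("CD2", "CG", "CB", "CA", 1.360, 131.1, _chi(2, 180.0)),
               ("CE1", "ND1", "CG", "CB", 1.320, 109.3, 180.0),
               ("NE2", "CD2", "CG", "CB", 1.370, 107.2, 180.0)],
}
# fmt: on

N_CHI = {
    "G": 0, "A": 0, "S": 1, "C": 1, "T": 1, "V": 1, "P": 2,
    "L": 2, "I": 2, "F": 2, "Y": 2, "W": 2, "D": 2, "N": 2, "H": 2,
    "M": 3, "E": 3, "Q": 3, "K": 4, "R": 4,
}


def build_sidechain(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, aa: str, chis: tuple[float, ...]
) -> np.ndarray:
    """Heavy-atom side-chain coordinates (k x 3, CB first) for amino acid ``aa``
    built onto the backbone frame (N, CA, C) with the given chi angles.

    Glycine returns an empty (0, 3) array.
    """
    topo = SIDECHAIN_TOPOLOGY[aa]
    coords: dict[str, np.ndarray] = {
        "N": np.asarray(n, float),
        "CA": np.asarray(ca, float),
        "C": np.asarray(c, float),
    }
    placed = []
    for name, parent, angle_ref, tors_ref, bond, angle, tors in topo:
        if isinstance(tors, tuple) and tors[0] == "chi":
            _, k, offset = tors
            if k > len(chis):
                raise ValueError(f"{aa} needs chi{k} but only {len(chis)} given")
            tors_val = chis[k - 1] + offset
        else:
            tors_val = float(tors)
        atom = place_atom(coords[tors_ref], coords[angle_ref], coords[parent], bond, angle, tors_val)
        coords[name] = atom
        placed.append(atom)
    if not placed:
        return np.zeros((0, 3))
    return np.stack(placed)
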
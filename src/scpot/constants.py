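"""Shared amino-acid tables and idealized backbone geometry constants."""

from __future__ import annotations

import numpy as np

# Canonical amino-acid order used for every 20-vector / 20x20 matrix in the package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
N_AA = 20

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is treated as methionine
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Idealized backbone internal coordinates (Engh-Huber-style averages), used by the
# synthetic backbone builder and the side-chain template builder.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# Ideal secondary-structure dihedrals (degrees).
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def aa_to_index(aa: str) -> int:
    """Map a one-letter amino-acid code to its canonical matrix index."""
    try:
        return AA_INDEX[aa]
    except KeyError:
        raise KeyError(f"not a canonical amino acid: {aa!r}") from None


def uniform_aa_freqs() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)
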
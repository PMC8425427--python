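"""Shared tables: amino-acid alphabets, hydrophobicity scale, vdW radii, backgrounds.

All tables are plain Python data shipped with the code so that no run ever
depends on an external database.
"""

from __future__ import annotations

import numpy as np

#: Canonical 20-letter amino-acid alphabet (fixed column order of all profiles).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP = "-"
UNKNOWN = "X"

#: Alphabet used by the coupling engine: 20 amino acids + gap state.
COUPLING_ALPHABET = AMINO_ACIDS + GAP
Q = len(COUPLING_ALPHABET)  # 21

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common non-standard residues mapped to their parent type
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y",
}
ONE_TO_THREE = {one: three for three, one in list(THREE_TO_ONE.items())[:20]}

#: Wimley-White whole-residue hydrophobicity scale (water -> POPC interface,
#: kcal/mol; positive = partitioning into water favoured).
WIMLEY_WHITE = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.96, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}

#: Chothia-style van der Waals radii by element (Angstrom). Unknown elements
#: fall back to :data:`DEFAULT_VDW_RADIUS`.
VDW_RADII = {
    "C": 1.76,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.8

#: Robinson & Robinson background amino-acid frequencies, in AMINO_ACIDS order.
BACKGROUND_FREQS = np.array([
    0.07805,  # A
    0.01925,  # C
    0.05364,  # D
    0.06295,  # E
    0.03856,  # F
    0.07377,  # G
    0.02199,  # H
    0.05142,  # I
    0.05744,  # K
    0.09019,  # L
    0.02243,  # M
    0.04487,  # N
    0.05203,  # P
    0.04264,  # Q
    0.05129,  # R
    0.07120,  # S
    0.05841,  # T
    0.06441,  # V
    0.01330,  # W
    0.03216,  # Y
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


def vdw_radius(element: str) -> float:
    """Van der Waals radius for *element*, with a fallback for unknowns."""
    return VDW_RADII.get(element.upper().strip(), DEFAULT_VDW_RADIUS)
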
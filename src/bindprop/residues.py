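"""Amino-acid reference tables shared across the package.

The canonical residue order used for every count vector, frequency table
and propensity vector in this package is the alphabetical order of the
three-letter codes below.  Index positions are stable API.
"""

from __future__ import annotations

import numpy as np

#: Canonical order of the 20 standard amino acids (3-letter codes).
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: 3-letter -> index into the canonical order.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AA = len(AMINO_ACIDS)

#: Number of non-hydrogen atoms per residue (backbone + side chain,
#: excluding terminal OXT).  Used for contacts-per-heavy-atom statistics.
HEAVY_ATOMS: dict[str, int] = {
    "ALA": 5, "ARG": 11, "ASN": 8, "ASP": 8, "CYS": 6,
    "GLN": 9, "GLU": 9, "GLY": 4, "HIS": 10, "ILE": 8,
    "LEU": 8, "LYS": 9, "MET": 8, "PHE": 11, "PRO": 7,
    "SER": 6, "THR": 7, "TRP": 14, "TYR": 12, "VAL": 7,
}

#: Backbone heavy-atom names.  OXT (C-terminal carboxylate oxygen) is
#: treated as backbone.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue names recognised as water.
WATER_NAMES = frozenset({"HOH", "DOD", "WAT", "H2O"})

#: Modified residues mapped to their parent amino acid by default.
DEFAULT_MODIFIED_RESIDUES: dict[str, str] = {
    "MSE": "MET",   # selenomethionine
    "CSE": "CYS",   # selenocysteine (legacy code)
    "SEC": "CYS",
}


def count_vector(resnames) -> np.ndarray:
    """Count residue types into the canonical 20-vector.

    Unknown residue names are ignored.
    """
    v = np.zeros(N_AA, dtype=np.int64)
    for name in resnames:
        i = AA_INDEX.get(name)
        if i is not None:
            v[i] += 1
    return v
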
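"""Residue alphabets, substitution scores and physicochemical groupings.

Coordinate convention: residue positions are 1-based inclusive everywhere
in this package, matching the standard way modification sites are reported.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

#: 20 standard amino acids, selenocysteine 'U', and the placeholder 'X'
#: used both for unknown residues and for out-of-protein window padding.
ALPHABET22 = "ACDEFGHIKLMNPQRSTVWYUX"

#: The 20 standard amino acids (the first 20 letters of ALPHABET22).
STANDARD20 = ALPHABET22[:20]

ALPHABET22_INDEX = {aa: i for i, aa in enumerate(ALPHABET22)}
STANDARD20_INDEX = {aa: i for i, aa in enumerate(STANDARD20)}

#: Secondary-structure states: coil, helix, strand, plus padding/unknown.
SS_ALPHABET = "CHEX"

#: Fixed 2-bit codebook for secondary-structure letters.
SS_CODEBOOK = {"C": (0, 0), "H": (0, 1), "E": (1, 0), "X": (1, 1)}


def is_valid_sequence(sequence: str) -> bool:
    """True if every character is in the 22-letter alphabet."""
    return bool(sequence) and all(c in ALPHABET22_INDEX for c in sequence)


@lru_cache(maxsize=1)
def blosum62_rows() -> np.ndarray:
    """BLOSUM62 substitution scores as a (22, 20) lookup table.

    Row i is the 20-entry score row (in STANDARD20 order) for residue
    ALPHABET22[i]; the 'U' and 'X' rows are all zero, so padded or unknown
    window positions contribute no substitution signal.
    """
    mat = substitution_matrices.load("BLOSUM62")
    table = np.zeros((22, 20), dtype=float)
    for i, a in enumerate(STANDARD20):
        for j, b in enumerate(STANDARD20):
            table[i, j] = mat[a, b]
    return table


@lru_cache(maxsize=1)
def ctd_groups() -> dict[str, list[str]]:
    """The 13 physicochemical property partitions used by the CTDC encoder.

    Each property maps the 20 standard residues into three disjoint groups
    (e.g. hydrophobicity: polar / neutral / hydrophobic). The table is the
    standard composition/transition/distribution grouping of the iLearn
    descriptor lineage, shipped as package data.
    """
    ref = resources.files("kglupred").joinpath("data/ctd_groups.json")
    groups: dict[str, list[str]] = json.loads(ref.read_text())
    for prop, triple in groups.items():
        joined = "".join(triple)
        if sorted(joined) != sorted(STANDARD20):
            raise ValueError(f"CTD property {prop!r} does not partition the 20 residues")
    return groups


@lru_cache(maxsize=1)
def ctd_group_index() -> dict[str, dict[str, int]]:
    """Per property, residue -> group index (0, 1 or 2)."""
    return {
        prop: {aa: g for g, members in enumerate(triple) for aa in members}
        for prop, triple in ctd_groups().items()
    }
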
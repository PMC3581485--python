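"""Amino-acid alphabet, background composition, and sequence encoding.

The 20-letter alphabet is ordered alphabetically by one-letter code. Ambiguous
or non-standard residues (B, Z, X, U, O, J) are mapped to a 21st code that is
scored at background frequency under both the profile and the null model, so
they contribute exactly zero bits.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
X_CODE = 20  # non-standard / unknown residue

GAP_CHARS = frozenset("-.")

CHARGED = "DEKR"
HYDROPHOBIC = "AILMFVW"

# Swiss-Prot-style database amino-acid composition (fractions, renormalised).
_BG = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

BACKGROUND_FREQS = np.array([_BG[aa] for aa in AMINO_ACIDS], dtype=np.float64)
BACKGROUND_FREQS /= BACKGROUND_FREQS.sum()

_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _ENCODE_TABLE[ord(_aa)] = _i
for _c in "BZXUOJ":
    _ENCODE_TABLE[ord(_c)] = X_CODE


def encode(residues: str) -> np.ndarray:
    """Encode an uppercase residue string as int8 codes (X_CODE for non-standard).

    Raises ValueError on characters outside the amino-acid alphabet.
    """
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[raw]
    if (codes < 0).any():
        bad = residues[int(np.argmax(codes < 0))]
        raise ValueError(f"invalid residue character {bad!r}")
    return codes


def sample_background(rng: np.random.Generator, n: int) -> str:
    """Draw n i.i.d. residues from the background composition."""
    idx = rng.choice(20, size=n, p=BACKGROUND_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)
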
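"""Amino-acid alphabet and the integer encoding used throughout.

Codes: 0 = structural gap/pad, 1-20 = the canonical amino acids in
alphabetical one-letter order (A=1 ... Y=20), 21 = unknown/nonstandard 'X'.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino acids, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

PAD_CODE: int = 0
UNKNOWN_CODE: int = 21
N_CODES: int = 22  # 0..21 inclusive

AA_TO_CODE: dict[str, int] = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
CODE_TO_AA: dict[int, str] = {i + 1: aa for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}


def encode_residue(aa: str) -> int:
    """Map a one-letter residue to its integer code (21 for anything unknown)."""
    return AA_TO_CODE.get(aa.upper(), UNKNOWN_CODE)


def encode_string(seq: str) -> np.ndarray:
    """Encode an amino-acid string to an int array of codes in [1, 21]."""
    return np.array([encode_residue(a) for a in seq], dtype=np.int64)


def decode_codes(codes) -> str:
    """Decode integer codes back to a string; pads (0) are dropped, 21 -> 'X'."""
    out = []
    for c in np.asarray(codes).ravel():
        c = int(c)
        if c == PAD_CODE:
            continue
        out.append("X" if c == UNKNOWN_CODE else AMINO_ACIDS[c - 1])
    return "".join(out)
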
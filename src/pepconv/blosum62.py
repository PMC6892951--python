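"""The extended 21x21 substitution table used for the 15x21 peptide encoding.

The 20x20 block is the canonical NCBI BLOSUM62 integer matrix, embedded
verbatim (row/column order = the package alphabet) and guarded by a checksum
so it cannot drift silently.  The padding residue X gets a row and column of
zeros except for the diagonal entry X-X, which is 1: X is an artificial
symbol related only to itself.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache

import numpy as np

from .alphabet import ALPHABET

# Canonical NCBI BLOSUM62, rows/columns in alphabet order A..V (no X).
_BLOSUM62_20x20 = (
    ( 4, -1, -2, -2,  0, -1, -1,  0, -2, -1, -1, -1, -1, -2, -1,  1,  0, -3, -2,  0),  # A
    (-1,  5,  0, -2, -3,  1,  0, -2,  0, -3, -2,  2, -1, -3, -2, -1, -1, -3, -2, -3),  # R
    (-2,  0,  6,  1, -3,  0,  0,  0,  1, -3, -3,  0, -2, -3, -2,  1,  0, -4, -2, -3),  # N
    (-2, -2,  1,  6, -3,  0,  2, -1, -1, -3, -4, -1, -3, -3, -1,  0, -1, -4, -3, -3),  # D
    ( 0, -3, -3, -3,  9, -3, -4, -3, -3, -1, -1, -3, -1, -2, -3, -1, -1, -2, -2, -1),  # C
    (-1,  1,  0,  0, -3,  5,  2, -2,  0, -3, -2,  1,  0, -3, -1,  0, -1, -2, -1, -2),  # Q
    (-1,  0,  0,  2, -4,  2,  5, -2,  0, -3, -3,  1, -2, -3, -1,  0, -1, -3, -2, -2),  # E
    ( 0, -2,  0, -1, -3, -2, -2,  6, -2, -4, -4, -2, -3, -3, -2,  0, -2, -2, -3, -3),  # G
    (-2,  0,  1, -1, -3,  0,  0, -2,  8, -3, -3, -1, -2, -1, -2, -1, -2, -2,  2, -3),  # H
    (-1, -3, -3, -3, -1, -3, -3, -4, -3,  4,  2, -3,  1,  0, -3, -2, -1, -3, -1,  3),  # I
    (-1, -2, -3, -4, -1, -2, -3, -4, -3,  2,  4, -2,  2,  0, -3, -2, -1, -2, -1,  1),  # L
    (-1,  2,  0, -1, -3,  1,  1, -2, -1, -3, -2,  5, -1, -3, -1,  0, -1, -3, -2, -2),  # K
    (-1, -1, -2, -3, -1,  0, -2, -3, -2,  1,  2, -1,  5,  0, -2, -1, -1, -1, -1,  1),  # M
    (-2, -3, -3, -3, -2, -3, -3, -3, -1,  0,  0, -3,  0,  6, -4, -2, -2,  1,  3, -1),  # F
    (-1, -2, -2, -1, -3, -1, -1, -2, -2, -3, -3, -1, -2, -4,  7, -1, -1, -4, -3, -2),  # P
    ( 1, -1,  1,  0, -1,  0,  0,  0, -1, -2, -2,  0, -1, -2, -1,  4,  1, -3, -2, -2),  # S
    ( 0, -1,  0, -1, -1, -1, -1, -2, -2, -1, -1, -1, -1, -2, -1,  1,  5, -2, -2,  0),  # T
    (-3, -3, -4, -4, -2, -2, -3, -2, -2, -3, -2, -3, -1,  1, -4, -3, -2, 11,  2, -3),  # W
    (-2, -2, -2, -3, -2, -1, -2, -3,  2, -1, -1, -2, -1,  3, -3, -2, -2,  2,  7, -1),  # Y
    ( 0, -3, -3, -3, -1, -2, -2, -3, -3,  3,  1, -2,  1, -1, -2, -2,  0, -3, -1,  4),  # V
)

# sha256 of the row-major comma-joined integers; recomputed at import.
_CHECKSUM = "d81640694dba3049bc0136cd1688098b0ab77feb97f16c6bc5c673e4845b69b5"


def _checksum(block) -> str:
    flat = ",".join(str(v) for row in block for v in row)
    return hashlib.sha256(flat.encode()).hexdigest()


@lru_cache(maxsize=1)
def _cached_table() -> np.ndarray:
    if _checksum(_BLOSUM62_20x20) != _CHECKSUM:
        raise RuntimeError("embedded BLOSUM62 block failed its integrity checksum")
    table = np.zeros((21, 21), dtype=np.int64)
    table[:20, :20] = np.asarray(_BLOSUM62_20x20, dtype=np.int64)
    table[20, 20] = 1  # X scores only against itself
    table.setflags(write=False)
    return table


def substitution_table() -> np.ndarray:
    """Return the 21x21 integer table over the package alphabet.

    Raises ``RuntimeError`` if the embedded block fails its checksum.
    The returned array is a cached read-only view; copy before mutating.
    """
    return _cached_table()


SUBSTITUTION_ALPHABET = ALPHABET
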
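"""The 21-letter peptide alphabet: 20 standard amino acids plus the padding residue X.

The ordering is fixed package-wide: it defines the sequence-index feature
(1..21) and the row/column order of the extended substitution matrix.
"""

from __future__ import annotations

ALPHABET: tuple[str, ...] = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V", "X",
)

PAD = "X"

STANDARD_AA: frozenset[str] = frozenset(ALPHABET[:-1])

#: symbol -> 1-based index in the fixed ordering ('A' -> 1 ... 'V' -> 20, 'X' -> 21)
SEQUENCE_INDEX: dict[str, int] = {aa: i + 1 for i, aa in enumerate(ALPHABET)}


class InvalidResidueError(ValueError):
    """A character outside the 21-letter alphabet (or X where raw input is required)."""


def sequence_index(symbol: str) -> int:
    """Return the 1-based alphabet index of ``symbol`` (1..21)."""
    try:
        return SEQUENCE_INDEX[symbol]
    except KeyError:
        raise InvalidResidueError(f"unknown residue {symbol!r}") from None
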
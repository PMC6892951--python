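"""Peptide validation and anchor-preserving length normalization to 15mer.

MHC class I ligands of length 8-15 are mapped onto a canonical 15-symbol
frame over the 21-letter alphabet (20 amino acids + the artificial padding
residue ``X``).  The placement rule keeps the two anchor-bearing segments of
the 9mer binding core — original residues 1-4 and 6-9 — free of internal
padding:

* L >= 9: residues occupy positions 1..L, the tail 15-L positions are X.
* L == 8: residues 1-4 sit on positions 1-4, a single X sits at position 5
  (so residues 5-8 land on core positions 6-9), then X-padding to 15.

All positions are 1-based, matching the anchor nomenclature of the field
(anchor positions 1, 4, 6, 7, 9 of the binding core).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .alphabet import PAD, STANDARD_AA, InvalidResidueError

MIN_LENGTH = 8
MAX_LENGTH = 15
NORMALIZED_LENGTH = 15


class PeptideLengthError(ValueError):
    """Peptide length outside the supported 8-15 range."""


class NormalizationError(ValueError):
    """A malformed normalized sequence (wrong length or stray symbols)."""


@dataclass(frozen=True)
class Peptide:
    """A validated raw peptide over the 20 standard amino acids."""

    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NormalizedPeptide:
    """A 15-symbol frame with padding metadata.

    ``x_positions`` are the 1-based positions holding X; stripping them
    recovers the original peptide in order.
    """

    sequence15: str
    original_length: int
    x_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.sequence15) != NORMALIZED_LENGTH:
            raise NormalizationError(
                f"normalized sequence must have {NORMALIZED_LENGTH} symbols, "
                f"got {len(self.sequence15)}"
            )


def validate_peptide(raw: str) -> Peptide:
    """Validate ``raw`` and return an uppercase :class:`Peptide`.

    Whitespace is trimmed and lowercase letters are uppercased.  Length must
    be 8-15 and every character one of the 20 standard amino-acid letters;
    ambiguity codes (B, Z, J, U, O) and X are rejected rather than mapped,
    because X is reserved for padding.
    """
    seq = raw.strip().upper()
    n = len(seq)
    if n < MIN_LENGTH or n > MAX_LENGTH:
        raise PeptideLengthError(
            f"peptide length {n} outside supported range "
            f"[{MIN_LENGTH}, {MAX_LENGTH}]: {seq!r}"
        )
    for pos, ch in enumerate(seq, start=1):
        if ch not in STANDARD_AA:
            raise InvalidResidueError(
                f"invalid residue {ch!r} at position {pos} in {seq!r}"
            )
    return Peptide(seq)


def normalize_to_15mer(p: Peptide | str) -> NormalizedPeptide:
    """Convert a validated 8-15mer into the canonical 15-symbol frame."""
    if isinstance(p, str):
        p = validate_peptide(p)
    seq = p.sequence
    L = p.length
    if L >= 9:
        padded = seq + PAD * (NORMALIZED_LENGTH - L)
    else:  # L == 8: single X at position 5 keeps residues 5-8 on core 6-9
        padded = seq[:4] + PAD + seq[4:] + PAD * (NORMALIZED_LENGTH - L - 1)
    x_positions = tuple(i + 1 for i, ch in enumerate(padded) if ch == PAD)
    return NormalizedPeptide(padded, L, x_positions)


def denormalize(np_: NormalizedPeptide) -> Peptide:
    """Strip padding and recover the original peptide."""
    seq = np_.sequence15
    if len(seq) != NORMALIZED_LENGTH:
        raise NormalizationError(f"expected {NORMALIZED_LENGTH} symbols, got {len(seq)}")
    stripped = seq.replace(PAD, "")
    if len(stripped) != np_.original_length:
        raise NormalizationError(
            f"X-stripped length {len(stripped)} does not match recorded "
            f"original_length {np_.original_length}"
        )
    return validate_peptide(stripped)


def read_peptides(path: str | Path) -> list[str]:
    """Read raw peptide sequences from plain text (one per line) or FASTA."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def normalize_batch(raws: Iterable[str]) -> Iterator[NormalizedPeptide]:
    for raw in raws:
        yield normalize_to_15mer(validate_peptide(raw))


def write_normalized_table(normalized: Iterable[NormalizedPeptide], path: str | Path) -> None:
    """Write a tab-delimited table: sequence15, original_length, x_positions."""
    with open(path, "w") as fh:
        fh.write("sequence15\toriginal_length\tx_positions\n")
        for np_ in normalized:
            xs = ",".join(str(i) for i in np_.x_positions)
            fh.write(f"{np_.sequence15}\t{np_.original_length}\t{xs}\n")
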
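"""Per-peptide feature matrices: 15x21 substitution encoding and 4x15 chemical encoding.

Two encodings of the normalized 15-symbol frame:

* **substitution** — each of the 15 positions is replaced by its row of the
  extended BLOSUM62 table, giving a 15x21 integer matrix (an X position is a
  one-hot row: zeros with a 1 in the X column).
* **chemical** — a 4x15 matrix whose rows are (1) the sequence index of each
  symbol (1..21, 21 iff X), (2) the Eisenberg consensus hydropathy value
  (0 for X), (3) the polarity class (0 none/X, 1 nonpolar aliphatic/aromatic,
  2 polar uncharged, 3 acidic, 4 basic), and (4) the original peptide length
  repeated across all 15 columns.
* **stacked** — the transposed substitution encoding (21x15) concatenated
  with the chemical matrix into 25x15, so both views feed one network.

All encoders emit channels x 15 (positions along the last axis) so the modes
are interchangeable as network input.  The encoders follow the sklearn
transformer protocol (``fit``/``transform`` on sequences of peptide strings).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import ALPHABET, InvalidResidueError, sequence_index
from .blosum62 import substitution_table
from .peptides import NormalizedPeptide, normalize_to_15mer, validate_peptide

#: Eisenberg consensus scale hydropathy values; padding residue X is 0.
HYDROPATHY: dict[str, float] = {
    "R": -2.5, "K": -1.5, "D": -0.9, "Q": -0.85, "N": -0.78, "E": -0.74,
    "H": 0.40, "S": -0.18, "T": -0.05, "P": 0.12, "Y": 0.26, "C": 0.29,
    "G": 0.48, "A": 0.62, "M": 0.64, "W": 0.81, "L": 1.1, "V": 1.1,
    "F": 1.2, "I": 1.4, "X": 0.0,
}

#: polarity classes: 0 none (X), 1 nonpolar, 2 polar uncharged,
#: 3 negatively charged (acidic), 4 positively charged (basic).
POLARITY_CLASS: dict[str, int] = {"X": 0}
for _aa in "AGILFPV":
    POLARITY_CLASS[_aa] = 1
for _aa in "NCQSTWYM":
    POLARITY_CLASS[_aa] = 2
for _aa in "DE":
    POLARITY_CLASS[_aa] = 3
for _aa in "RHK":
    POLARITY_CLASS[_aa] = 4

ENCODING_MODES = ("chemical", "substitution", "stacked")

#: channels x positions shape of each encoding mode
ENCODING_SHAPES = {"chemical": (4, 15), "substitution": (21, 15), "stacked": (25, 15)}


def hydropathy(symbol: str) -> float:
    """Eisenberg consensus hydropathy of ``symbol`` (0 for X)."""
    try:
        return HYDROPATHY[symbol]
    except KeyError:
        raise InvalidResidueError(f"unknown residue {symbol!r}") from None


def polarity_class(symbol: str) -> int:
    """Polarity class label of ``symbol`` in 0..4 (0 for X)."""
    try:
        return POLARITY_CLASS[symbol]
    except KeyError:
        raise InvalidResidueError(f"unknown residue {symbol!r}") from None


def _as_normalized(p: NormalizedPeptide | str) -> NormalizedPeptide:
    if isinstance(p, str):
        return normalize_to_15mer(validate_peptide(p))
    return p


def encode_substitution(p: NormalizedPeptide | str) -> np.ndarray:
    """15x21 matrix: row i is the substitution-table row of the symbol at position i."""
    np_ = _as_normalized(p)
    table = substitution_table()
    rows = [table[sequence_index(ch) - 1] for ch in np_.sequence15]
    return np.stack(rows)


def encode_chemical(p: NormalizedPeptide | str) -> np.ndarray:
    """4x15 matrix of (sequence index, hydropathy, polarity class, length)."""
    np_ = _as_normalized(p)
    seq = np_.sequence15
    mat = np.zeros((4, 15), dtype=np.float64)
    mat[0] = [sequence_index(ch) for ch in seq]
    mat[1] = [hydropathy(ch) for ch in seq]
    mat[2] = [polarity_class(ch) for ch in seq]
    mat[3] = np_.original_length
    return mat


def _encode_one(p: NormalizedPeptide | str, mode: str) -> np.ndarray:
    if mode == "chemical":
        return encode_chemical(p)
    if mode == "substitution":
        return encode_substitution(p).T.astype(np.float64)
    if mode == "stacked":
        return np.vstack([encode_substitution(p).T.astype(np.float64), encode_chemical(p)])
    raise ValueError(f"unknown encoding mode {mode!r}; expected one of {ENCODING_MODES}")


class BatchEncodingError(ValueError):
    """One or more peptides in a batch failed validation.

    ``errors`` maps 0-based item index to the underlying error message;
    nothing is silently dropped.
    """

    def __init__(self, errors: dict[int, str]):
        self.errors = errors
        lines = "; ".join(f"item {i}: {msg}" for i, msg in sorted(errors.items()))
        super().__init__(f"{len(errors)} peptide(s) failed encoding: {lines}")


def encode_batch(
    peptides: Iterable[NormalizedPeptide | str], mode: str = "chemical"
) -> np.ndarray:
    """Stack per-peptide encodings into an (n, channels, 15) array.

    All peptides are validated up front; any failure raises
    :class:`BatchEncodingError` listing every offending item.
    An empty input yields an empty stack of the right trailing shape.
    """
    if mode not in ENCODING_MODES:
        raise ValueError(f"unknown encoding mode {mode!r}; expected one of {ENCODING_MODES}")
    items = list(peptides)
    mats, errors = [], {}
    for i, p in enumerate(items):
        try:
            mats.append(_encode_one(p, mode))
        except (ValueError, InvalidResidueError) as exc:
            errors[i] = str(exc)
    if errors:
        raise BatchEncodingError(errors)
    if not mats:
        return np.empty((0, *ENCODING_SHAPES[mode]), dtype=np.float64)
    return np.stack(mats)


class PeptideEncoder(BaseEstimator, TransformerMixin):
    """Transform peptide strings into stacked feature tensors.

    Parameters
    ----------
    mode : {"chemical", "substitution", "stacked"}
        Which feature matrix to emit per peptide.
    standardize : bool
        If True, standardize each channel to zero mean / unit variance over
        the fitted data (off by default: raw table values are the faithful
        encoding).
    """

    def __init__(self, mode: str = "chemical", standardize: bool = False):
        self.mode = mode
        self.standardize = standardize

    def fit(self, X: Sequence[str], y=None) -> "PeptideEncoder":
        if self.mode not in ENCODING_MODES:
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if self.standardize:
            stack = encode_batch(X, self.mode)
            # per-channel moments over peptides and positions
            self.channel_mean_ = stack.mean(axis=(0, 2)) if len(stack) else np.zeros(
                ENCODING_SHAPES[self.mode][0]
            )
            sd = stack.std(axis=(0, 2)) if len(stack) else np.ones(
                ENCODING_SHAPES[self.mode][0]
            )
            self.channel_std_ = np.where(sd > 0, sd, 1.0)
        self.n_channels_ = ENCODING_SHAPES[self.mode][0]
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        stack = encode_batch(X, self.mode)
        if self.standardize:
            stack = (stack - self.channel_mean_[None, :, None]) / self.channel_std_[
                None, :, None
            ]
        return stack


class SubstitutionEncoder(PeptideEncoder):
    def __init__(self, standardize: bool = False):
        super().__init__(mode="substitution", standardize=standardize)

    def get_params(self, deep: bool = True):
        return {"standardize": self.standardize}


class ChemicalEncoder(PeptideEncoder):
    def __init__(self, standardize: bool = False):
        super().__init__(mode="chemical", standardize=standardize)

    def get_params(self, deep: bool = True):
        return {"standardize": self.standardize}


class StackedEncoder(PeptideEncoder):
    def __init__(self, standardize: bool = False):
        super().__init__(mode="stacked", standardize=standardize)

    def get_params(self, deep: bool = True):
        return {"standardize": self.standardize}


def write_feature_blocks(stack: np.ndarray, path) -> None:
    """Write a batch of feature matrices as delimited text, one blank-line-separated
    block per peptide."""
    with open(path, "w") as fh:
        for i, mat in enumerate(stack):
            fh.write(f"# peptide {i}\n")
            for row in mat:
                fh.write("\t".join(f"{v:g}" for v in row) + "\n")
            fh.write("\n")
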
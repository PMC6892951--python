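"""Peptide-length-preference probe.

A trained allele model is probed with a uniform random peptide set —
by default 10,000 peptides, 1,250 of each length 8 to 15, residues drawn
uniformly over the 20 standard amino acids.  The top-scoring 2% are
selected and their length distribution reported; the modal length is the
model's apparent length preference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import ALPHABET

LENGTH_RANGE = tuple(range(8, 16))
DEFAULT_PER_LENGTH = 1250
DEFAULT_FRACTION = 0.02


@dataclass
class ProbeSet:
    peptides: list[str]
    lengths: list[int]
    per_length_count: int
    seed: int


@dataclass
class LengthPreferenceReport:
    allele: str
    fraction: float
    n_selected: int
    counts: dict[int, int] = field(default_factory=dict)
    proportions: dict[int, float] = field(default_factory=dict)
    modal_length: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "allele": self.allele,
            "fraction": self.fraction,
            "n_selected": self.n_selected,
            "counts": {str(k): v for k, v in self.counts.items()},
            "proportions": {str(k): v for k, v in self.proportions.items()},
            "modal_length": self.modal_length,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("length\tcount\tproportion\n")
            for L in LENGTH_RANGE:
                fh.write(f"{L}\t{self.counts.get(L, 0)}\t{self.proportions.get(L, 0.0):.6f}\n")


def generate_probe(per_length_count: int = DEFAULT_PER_LENGTH, seed: int = 0) -> ProbeSet:
    """Random probe peptides: ``per_length_count`` per length 8..15,
    residues uniform over the 20 standard amino acids, deterministic under seed."""
    if per_length_count < 1:
        raise ValueError(f"per_length_count must be >= 1, got {per_length_count}")
    rng = np.random.default_rng(seed)
    residues = np.array(ALPHABET[:-1])
    peptides, lengths = [], []
    for L in LENGTH_RANGE:
        draws = rng.integers(0, 20, size=(per_length_count, L))
        for row in draws:
            peptides.append("".join(residues[row]))
            lengths.append(L)
    return ProbeSet(peptides, lengths, per_length_count, seed)


def top_fraction(scores: Sequence[float], fraction: float = DEFAULT_FRACTION) -> np.ndarray:
    """Indices of the ceil(fraction*N) highest scores, ties broken by stable
    input order (earlier items win)."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("cannot select from an empty probe")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_select = math.ceil(fraction * s.size)
    order = np.argsort(-s, kind="stable")  # stable: equal scores keep input order
    return np.sort(order[:n_select])


def length_distribution(
    lengths: Sequence[int], allele: str = "", fraction: float = DEFAULT_FRACTION
) -> LengthPreferenceReport:
    """Summarize the selected peptides' original lengths."""
    L = np.asarray(lengths, dtype=int)
    if L.size == 0:
        raise ValueError("cannot report on an empty selection")
    counts = {int(v): int(c) for v, c in zip(*np.unique(L, return_counts=True))}
    proportions = {k: v / L.size for k, v in counts.items()}
    modal = max(counts, key=lambda k: (counts[k], -k))
    return LengthPreferenceReport(
        allele=allele,
        fraction=fraction,
        n_selected=int(L.size),
        counts=counts,
        proportions=proportions,
        modal_length=modal,
    )


def probe_model(
    model,
    allele: str = "",
    per_length_count: int = DEFAULT_PER_LENGTH,
    fraction: float = DEFAULT_FRACTION,
    seed: int = 0,
) -> LengthPreferenceReport:
    """End-to-end probe: generate, score with ``model`` (``decision_scores``
    or ``predict_proba``), select the top fraction, and report lengths."""
    probe = generate_probe(per_length_count, seed)
    if hasattr(model, "decision_scores"):
        scores = model.decision_scores(probe.peptides)
    else:
        scores = model.predict_proba(probe.peptides)[:, 1]
    selected = top_fraction(scores, fraction)
    lengths = [probe.lengths[i] for i in selected]
    return length_distribution(lengths, allele=allele, fraction=fraction)
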
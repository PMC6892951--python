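"""F1 and AUC metrics, per-allele cross-validation, and cohort summaries.

F1 is computed directly from confusion counts as 2TP / (2TP + FN + FP)
(the harmonic mean of precision and recall); AUC is the probability that a
random positive outranks a random negative, ties counted half.  Models are
evaluated per allele with a seeded shuffle + k-fold cross-validation
(default k = 5) and summarized across alleles by mean / median / sample
standard deviation, with binned score distributions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from .data import LabeledExample, shuffle_and_split


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. single-class AUC)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must align")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
    )


def f1_score(c: ConfusionCounts) -> float:
    """F1 = 2TP / (2TP + FN + FP); 0 when the denominator vanishes.

    The degenerate case (no positives predicted or present) is flagged on
    the return value via :func:`f1_is_degenerate` rather than raising, so
    cohort means stay defined.
    """
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return 0.0
    return 2 * c.tp / denom


def f1_is_degenerate(c: ConfusionCounts) -> bool:
    return (2 * c.tp + c.fn + c.fp) == 0


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(score of random positive > score of random negative),
    ties counted half.  Raises :class:`UndefinedMetricError` without both classes."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUC is undefined when only one class is present")
    return float(roc_auc_score(y, s))


@dataclass
class AlleleMetrics:
    allele: str
    fold_f1: list[float] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1)) if self.fold_f1 else math.nan

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc)) if self.fold_auc else math.nan


def cross_validate(
    peptides: Sequence[str],
    labels: Sequence[int],
    estimator,
    k: int = 5,
    seed: int = 0,
    allele: str = "",
    threshold: float = 0.5,
) -> AlleleMetrics:
    """Shuffled k-fold cross-validation of a peptide classifier.

    ``estimator`` is an unfitted sklearn-style classifier over peptide
    strings (cloned per fold).  F1 is computed at the given probability
    cut; AUC on the continuous scores.  Folds whose training data lack a
    class, or whose held-out data lack a class (AUC undefined), are
    recorded in ``skipped_folds`` instead of being silently averaged.
    """
    peptides = list(peptides)
    y = np.asarray(labels, dtype=int)
    folds = shuffle_and_split(len(peptides), k=k, seed=seed)
    metrics = AlleleMetrics(allele=allele)
    all_idx = np.arange(len(peptides))
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            metrics.skipped_folds.append(i)
            continue
        model = clone(estimator)
        model.fit([peptides[j] for j in train_idx], y_tr)
        scores = model.predict_proba([peptides[j] for j in test_idx])[:, 1]
        preds = (scores >= threshold).astype(int)
        metrics.fold_f1.append(f1_score(confusion_counts(y_te, preds)))
        metrics.fold_auc.append(auc_score(y_te, scores))
    return metrics


def evaluate_alleles(
    examples: Sequence[LabeledExample],
    estimator,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> list[AlleleMetrics]:
    """Cross-validate every allele present in ``examples`` (original sequences
    are recovered from the normalized frames)."""
    by_allele: dict[str, list[LabeledExample]] = {}
    for ex in examples:
        by_allele.setdefault(ex.allele, []).append(ex)
    out = []
    for allele in sorted(by_allele):
        exs = by_allele[allele]
        peps = [ex.peptide.sequence15.replace("X", "") for ex in exs]
        labels = [ex.label for ex in exs]
        out.append(
            cross_validate(peps, labels, estimator, k=k, seed=seed, allele=allele,
                           threshold=threshold)
        )
    return out


#: F1 report bins: below 0.5, 0.5-0.9, above 0.9
F1_BIN_EDGES = (0.5, 0.9)


@dataclass
class CohortSummary:
    n_alleles: int
    mean_f1: float
    median_f1: float
    sd_f1: float
    mean_auc: float
    median_auc: float
    sd_auc: float
    f1_bins: dict[str, float]
    auc_deciles: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _sample_sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def summarize_cohort(metrics: Sequence[AlleleMetrics]) -> CohortSummary:
    """Across-allele summary of per-allele mean F1 and AUC.

    Mean / median / sample standard deviation (n-1; 0 for a single
    allele), an F1 histogram over the bins <0.5, 0.5-0.9, >0.9, and an
    AUC decile histogram.
    """
    if not metrics:
        raise ValueError("cannot summarize an empty metrics list")
    f1 = np.array([m.mean_f1 for m in metrics])
    auc = np.array([m.mean_auc for m in metrics])
    lo, hi = F1_BIN_EDGES
    f1_bins = {
        f"<{lo}": float(np.mean(f1 < lo)),
        f"{lo}-{hi}": float(np.mean((f1 >= lo) & (f1 <= hi))),
        f">{hi}": float(np.mean(f1 > hi)),
    }
    decile_edges = np.linspace(0, 1, 11)
    counts, _ = np.histogram(auc, bins=decile_edges)
    auc_deciles = {
        f"{decile_edges[i]:.1f}-{decile_edges[i+1]:.1f}": int(counts[i])
        for i in range(10)
    }
    return CohortSummary(
        n_alleles=len(metrics),
        mean_f1=float(np.mean(f1)),
        median_f1=float(np.median(f1)),
        sd_f1=_sample_sd(f1),
        mean_auc=float(np.mean(auc)),
        median_auc=float(np.median(auc)),
        sd_auc=_sample_sd(auc),
        f1_bins=f1_bins,
        auc_deciles=auc_deciles,
    )


def write_metrics_table(metrics: Sequence[AlleleMetrics], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("allele\tfold\tf1\tauc\n")
        for m in metrics:
            for i, (f1v, aucv) in enumerate(zip(m.fold_f1, m.fold_auc)):
                fh.write(f"{m.allele}\t{i}\t{f1v:.6f}\t{aucv:.6f}\n")
            fh.write(f"{m.allele}\tmean\t{m.mean_f1:.6f}\t{m.mean_auc:.6f}\n")
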
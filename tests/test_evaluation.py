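"""F1 and AUC against independent oracles; cross-validation bookkeeping; cohort summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score as sklearn_f1

from pepconv.evaluation import (
    AlleleMetrics,
    ConfusionCounts,
    UndefinedMetricError,
    auc_score,
    confusion_counts,
    cross_validate,
    f1_is_degenerate,
    f1_score,
    summarize_cohort,
    write_metrics_table,
)


def _brute_force_f1(tp, fp, fn):
    """Recompute F1 from expanded (label, prediction) pairs via precision/recall."""
    labels = [1] * tp + [0] * fp + [1] * fn
    preds = [1] * tp + [1] * fp + [0] * fn
    pred_pos = sum(preds)
    actual_pos = sum(labels)
    hits = sum(1 for y, p in zip(labels, preds) if y == p == 1)
    if pred_pos == 0 or actual_pos == 0:
        return 0.0
    precision, recall = hits / pred_pos, hits / actual_pos
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _pair_counting_auc(labels, scores):
    """Exhaustive Mann-Whitney statistic over all positive-negative pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = wins = 0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                wins += 1
            elif p == n:
                wins += 0.5
    return wins / total


class TestF1:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (5, 0, 0, 1.0),
        (0, 2, 3, 0.0),
        (3, 1, 2, 6 / 9),
    ])
    def test_direct_values(self, tp, fp, fn, expected):
        assert f1_score(ConfusionCounts(tp, fp, fn, 0)) == pytest.approx(expected)

    def test_matches_brute_force_exhaustively(self):
        """Every confusion matrix with entries <= 20 agrees with the
        expanded-pair recomputation."""
        for tp, fp, fn in itertools.product(range(21), repeat=3):
            got = f1_score(ConfusionCounts(tp, fp, fn, 0))
            assert got == pytest.approx(_brute_force_f1(tp, fp, fn)), (tp, fp, fn)

    def test_matches_sklearn_on_random_calls(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, size=30)
            p = rng.integers(0, 2, size=30)
            if y.sum() == 0 and p.sum() == 0:
                continue
            got = f1_score(confusion_counts(y, p))
            assert got == pytest.approx(sklearn_f1(y, p))

    def test_empty_denominator_is_flagged_zero(self):
        c = ConfusionCounts(0, 0, 0, 10)
        assert f1_score(c) == 0.0
        assert f1_is_degenerate(c)
        assert not f1_is_degenerate(ConfusionCounts(1, 0, 0, 9))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_counts_sum_to_total(self):
        c = confusion_counts([1, 1, 0, 0, 1], [1, 0, 1, 0, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)
        assert c.total == 5


auc_cases = st.integers(2, 12).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ys: 0 < sum(ys) < len(ys)
        ),
        st.lists(st.integers(0, 5).map(lambda v: v / 5), min_size=n, max_size=n),
    )
)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_is_half(self):
        assert auc_score([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc_score([1, 1, 1], [0.1, 0.2, 0.3])

    def test_six_example_toy_set_matches_pair_counting(self):
        labels = [1, 0, 1, 0, 1, 0]
        scores = [0.9, 0.8, 0.7, 0.7, 0.2, 0.1]
        assert auc_score(labels, scores) == pytest.approx(
            _pair_counting_auc(labels, scores)
        )

    @given(auc_cases)
    def test_matches_exhaustive_pair_counting(self, case):
        labels, scores = case
        assert auc_score(labels, scores) == pytest.approx(
            _pair_counting_auc(labels, scores)
        )


class _LengthScorer(BaseEstimator, ClassifierMixin):
    """Fast stand-in classifier: score = how close the length is to 9."""

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p1 = np.array([1.0 / (1.0 + abs(len(p) - 9)) for p in X])
        return np.column_stack([1 - p1, p1])


class _MotifScorer(BaseEstimator, ClassifierMixin):
    """Stand-in scoring by anchor-pocket matches of the default planted motif."""

    ANCHORS = {1: "RK", 4: "DE", 6: "IL", 9: "FW"}

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p1 = []
        for pep in X:
            frame = pep if len(pep) >= 9 else pep[:4] + "X" + pep[4:]
            hits = sum(
                1 for pos, res in self.ANCHORS.items()
                if pos <= len(frame) and frame[pos - 1] in res
            )
            p1.append(hits / 4 * 0.98 + 0.01)
        p1 = np.asarray(p1)
        return np.column_stack([1 - p1, p1])


class TestCrossValidate:
    def test_reports_exactly_k_fold_metrics(self, rng):
        peps = ["ACDEFGHIK"] * 50 + ["ACDEFGHIKL"] * 50
        labels = rng.permutation([0, 1] * 50)
        m = cross_validate(peps, labels, _LengthScorer(), k=5, seed=0)
        assert len(m.fold_f1) + len(m.skipped_folds) == 5
        assert len(m.fold_auc) == len(m.fold_f1)

    def test_strong_motif_recovers_signal(self):
        from pepconv.synth import MotifSpec, generate_allele_dataset

        ds = generate_allele_dataset(MotifSpec(), n=500, seed=31)
        m = cross_validate(ds.peptides, ds.labels, _MotifScorer(), k=5, seed=0)
        assert m.mean_auc > 0.85

    def test_permuted_labels_score_at_chance(self, rng):
        from pepconv.synth import MotifSpec, generate_allele_dataset

        ds = generate_allele_dataset(MotifSpec(), n=500, seed=32)
        shuffled = rng.permutation(ds.labels)
        m = cross_validate(ds.peptides, shuffled, _MotifScorer(), k=5, seed=0)
        assert 0.4 <= m.mean_auc <= 0.6

    def test_determinism_under_seed(self):
        peps = ["ACDEFGHIK"] * 30 + ["ACDEFGHIKL"] * 30
        labels = [0, 1] * 30
        a = cross_validate(peps, labels, _LengthScorer(), k=5, seed=4)
        b = cross_validate(peps, labels, _LengthScorer(), k=5, seed=4)
        assert a.fold_f1 == b.fold_f1 and a.fold_auc == b.fold_auc


class TestCohortSummary:
    def _metrics(self, f1s, aucs=None):
        aucs = aucs if aucs is not None else f1s
        return [
            AlleleMetrics(f"A{i}", fold_f1=[v], fold_auc=[a])
            for i, (v, a) in enumerate(zip(f1s, aucs))
        ]

    def test_single_allele_convention(self):
        s = summarize_cohort(self._metrics([0.7]))
        assert s.mean_f1 == s.median_f1 == 0.7
        assert s.sd_f1 == 0.0

    def test_f1_bins(self):
        s = summarize_cohort(self._metrics([0.4, 0.6, 0.95]))
        assert s.f1_bins[">0.9"] == pytest.approx(1 / 3)
        assert s.f1_bins["<0.5"] == pytest.approx(1 / 3)
        assert s.f1_bins["0.5-0.9"] == pytest.approx(1 / 3)

    def test_statistics_match_direct_recomputation(self, rng):
        for _ in range(50):
            f1s = rng.random(rng.integers(2, 12))
            s = summarize_cohort(self._metrics(list(f1s)))
            assert s.mean_f1 == pytest.approx(float(np.mean(f1s)))
            assert s.median_f1 == pytest.approx(float(np.median(f1s)))
            assert s.sd_f1 == pytest.approx(float(np.std(f1s, ddof=1)))

    def test_permutation_invariance(self, rng):
        f1s = list(rng.random(7))
        a = summarize_cohort(self._metrics(f1s))
        b = summarize_cohort(self._metrics(f1s[::-1]))
        assert a.mean_f1 == pytest.approx(b.mean_f1)
        assert a.sd_auc == pytest.approx(b.sd_auc)
        assert a.f1_bins == b.f1_bins

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_auc_deciles_count_alleles(self):
        s = summarize_cohort(self._metrics([0.55, 0.52, 0.95]))
        assert s.auc_deciles["0.5-0.6"] == 2
        assert s.auc_deciles["0.9-1.0"] == 1

    def test_metrics_table_output(self, tmp_path):
        write_metrics_table(self._metrics([0.5, 0.7]), tmp_path / "m.tsv")
        text = (tmp_path / "m.tsv").read_text()
        assert "A0\tmean\t0.500000" in text
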
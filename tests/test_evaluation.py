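"""Negative sampling, fold construction and the metric suite."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtifusion.evaluation import (
    compute_metrics,
    confusion_counts,
    f1_score,
    make_folds,
    roc_auc,
    sample_negatives,
)


class TestSampleNegatives:
    positives = [("dr:0", "t:0"), ("dr:1", "t:1"), ("dr:2", "t:2")]
    drugs = [f"dr:{i}" for i in range(5)]
    targets = [f"t:{i}" for i in range(5)]

    def test_balanced_count_and_disjoint(self):
        neg = sample_negatives(self.positives, self.drugs, self.targets, seed=0)
        assert len(neg) == len(self.positives)
        assert not set(neg) & set(self.positives)

    def test_reproducible_and_seed_sensitive(self):
        n1 = sample_negatives(self.positives, self.drugs, self.targets, n=10, seed=1)
        n2 = sample_negatives(self.positives, self.drugs, self.targets, n=10, seed=1)
        assert n1 == n2
        different = any(
            sample_negatives(self.positives, self.drugs, self.targets, n=10, seed=s) != n1
            for s in range(2, 8)
        )
        assert different

    def test_insufficient_candidates_rejected(self):
        with pytest.raises(ValueError):
            sample_negatives(self.positives, self.drugs, self.targets, n=23, seed=0)

    def test_all_candidates_when_n_equals_grid(self):
        neg = sample_negatives(self.positives, self.drugs, self.targets, n=22, seed=3)
        assert len(set(neg)) == 22


class TestMakeFolds:
    def test_split_sizes_7_1_2(self):
        labels = [0, 1] * 50
        folds = make_folds(labels, k=5, seed=0)
        assert len(folds) == 5
        for f in folds:
            assert abs(len(f.test_idx) - 20) <= 1
            assert abs(len(f.train_idx) - 70) <= 1
            assert abs(len(f.val_idx) - 10) <= 1
            assert len(f.train_idx) + len(f.val_idx) + len(f.test_idx) == 100

    def test_test_splits_partition_all_pairs(self):
        labels = [0, 1] * 30
        folds = make_folds(labels, k=5, seed=1)
        all_test = np.concatenate([f.test_idx for f in folds])
        assert sorted(all_test) == list(range(60))

    def test_within_fold_disjointness(self):
        labels = [0, 1] * 30
        for f in make_folds(labels, k=5, seed=2):
            sets = [set(f.train_idx), set(f.val_idx), set(f.test_idx)]
            assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_stratification_on_60_40_mix(self):
        labels = [1] * 60 + [0] * 40
        for f in make_folds(labels, k=5, seed=3):
            for idx in (f.train_idx, f.val_idx, f.test_idx):
                frac = np.mean([labels[i] for i in idx])
                assert abs(frac - 0.6) <= 0.05 + 1e-9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            make_folds([0, 1] * 3, k=5)


class TestConfusionCounts:
    def test_simple_case(self):
        assert confusion_counts([1, 0], [0.9, 0.1]) == (1, 1, 0, 0)

    def test_all_negative_scores_count_fn(self):
        tp, tn, fp, fn = confusion_counts([1, 0, 0], [0.0, 0.0, 0.0])
        assert (tp, fn) == (0, 1) and (tn, fp) == (2, 0)

    def test_matches_loop_oracle_on_random_data(self, rng):
        y = rng.integers(0, 2, size=1000)
        s = rng.random(1000)
        tp, tn, fp, fn = confusion_counts(y, s)
        otp = otn = ofp = ofn = 0
        for yi, si in zip(y, s):
            pred = si >= 0.5
            if pred and yi:
                otp += 1
            elif pred and not yi:
                ofp += 1
            elif not pred and yi:
                ofn += 1
            else:
                otn += 1
        assert (tp, tn, fp, fn) == (otp, otn, ofp, ofn)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([], [])


class TestComputeMetrics:
    def test_hand_computed_example(self):
        m = compute_metrics((9, 8, 1, 2))
        assert m.acc == pytest.approx(0.85)
        assert m.prec == pytest.approx(0.9)
        assert m.sen == pytest.approx(0.8182, abs=5e-5)
        assert m.f1 == pytest.approx(0.8571, abs=5e-5)
        assert m.mcc == pytest.approx(0.7035, abs=5e-5)

    def test_perfect_classifier(self):
        m = compute_metrics((10, 10, 0, 0))
        assert (m.acc, m.prec, m.sen, m.f1, m.mcc) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_degenerate_denominators_are_zero(self):
        m = compute_metrics((0, 5, 0, 5))
        assert m.prec == 0.0 and m.sen == 0.0 and m.f1 == 0.0 and m.mcc == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics((-1, 1, 1, 1))

    @given(
        tp=st.integers(0, 50),
        tn=st.integers(0, 50),
        fp=st.integers(0, 50),
        fn=st.integers(0, 50),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_rational_arithmetic_oracle(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        m = compute_metrics((tp, tn, fp, fn))
        total = Fraction(tp + tn, tp + tn + fp + fn)
        assert m.acc == pytest.approx(float(total))
        prec = Fraction(tp, tp + fp) if tp + fp else Fraction(0)
        sen = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
        assert m.prec == pytest.approx(float(prec))
        assert m.sen == pytest.approx(float(sen))
        f1 = 2 * prec * sen / (prec + sen) if prec + sen else Fraction(0)
        assert m.f1 == pytest.approx(float(f1))
        denom2 = (tp + fp) * (tn + fn) * (tn + fp) * (tp + fn)
        mcc = (tp * tn - fp * fn) / np.sqrt(denom2) if denom2 else 0.0
        assert m.mcc == pytest.approx(float(mcc))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_negated_scores_flip_auc(self):
        y = [0, 1, 0, 1, 1]
        s = [0.3, 0.6, 0.1, 0.8, 0.5]
        assert roc_auc(y, s) == pytest.approx(1 - roc_auc(y, [-x for x in s]))

    def test_matches_concordance_oracle(self, rng):
        y = rng.integers(0, 2, size=50)
        while y.sum() in (0, 50):
            y = rng.integers(0, 2, size=50)
        s = rng.random(50)
        conc = 0.0
        npairs = 0
        for i in range(50):
            for j in range(50):
                if y[i] == 1 and y[j] == 0:
                    npairs += 1
                    conc += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
        assert roc_auc(y, s) == pytest.approx(conc / npairs, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.4])


def test_f1_from_precision_and_sensitivity():
    assert f1_score(0.9, 9 / 11) == pytest.approx(0.8571, abs=5e-5)
    assert f1_score(0.0, 0.0) == 0.0
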
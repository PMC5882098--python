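"""Aggregation rules, confusion metrics, ROC/AUC, kappa, the t- and KS
tests, and patient-level splits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hfhisto.aggregate_eval import (
    cohens_kappa,
    confusion_metrics,
    crossval_split,
    image_prediction,
    ks_compare,
    one_sample_ttest,
    patient_diagnosis,
    patient_probability,
    roc_auc,
    train_test_split_patients,
    unpaired_ttest,
)
from hfhisto.errors import DegenerateInputError, InvalidArgumentError, InvalidDataError


class TestImagePrediction:
    def test_strictly_greater_than_fifty_percent(self):
        assert image_prediction(0.51) is True
        assert image_prediction(0.50) is False
        assert image_prediction(0.0) is False
        assert image_prediction(1.0) is True

    def test_call_flips_exactly_once_on_a_grid(self):
        calls = [image_prediction(p) for p in np.linspace(0, 1, 201)]
        flips = sum(a != b for a, b in zip(calls, calls[1:]))
        assert flips == 1 and calls[100] is False and calls[101] is True

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            image_prediction(1.2)


class TestPatientAggregation:
    def test_fraction_of_failing_calls(self):
        assert patient_probability([True] * 6 + [False] * 5) == pytest.approx(6 / 11)
        assert patient_probability([True] * 4) == 1.0
        with pytest.raises(DegenerateInputError):
            patient_probability([])

    @given(st.lists(st.booleans(), min_size=1, max_size=30), st.randoms())
    def test_invariant_to_call_order(self, calls, rnd):
        shuffled = calls[:]
        rnd.shuffle(shuffled)
        assert patient_probability(calls) == patient_probability(shuffled)

    def test_majority_vote_on_eleven_images(self):
        assert patient_diagnosis(6 / 11) is True
        assert patient_diagnosis(5 / 11) is False
        assert patient_diagnosis(0.5) is False  # strict tie policy

    def test_agrees_with_direct_majority_on_all_five_image_patterns(self):
        for pattern in itertools.product([0, 1], repeat=5):
            expected = sum(pattern) > len(pattern) / 2
            assert patient_diagnosis(patient_probability([bool(c) for c in pattern])) == expected


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        truths = np.array([1] * 10 + [0] * 10)
        calls = np.array([1] * 8 + [0] * 2 + [0] * 9 + [1] * 1)
        r = confusion_metrics(calls, truths, positive_class=1)
        assert (r.tp, r.fn, r.tn, r.fp) == (8, 2, 9, 1)
        assert r.sensitivity == pytest.approx(0.8)
        assert r.specificity == pytest.approx(0.9)
        assert r.accuracy == pytest.approx(0.85)
        assert r.ppv == pytest.approx(8 / 9)

    def test_perfect_calls_score_one_everywhere(self):
        t = np.array([1, 0, 1, 0, 1])
        r = confusion_metrics(t, t, positive_class=1)
        assert (r.accuracy, r.sensitivity, r.specificity, r.ppv) == (1.0, 1.0, 1.0, 1.0)

    def test_random_calls_near_half_accuracy(self, rng):
        n = 10_000
        r = confusion_metrics(rng.integers(0, 2, n), rng.integers(0, 2, n), positive_class=1)
        assert abs(r.accuracy - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_undefined_ratio_is_nan_with_warning_not_zero(self):
        truths = np.array([1, 1, 1])
        calls = np.array([0, 0, 0])  # no positive calls, no negatives in truth
        with pytest.warns(UserWarning):
            r = confusion_metrics(calls, truths, positive_class=1)
        assert np.isnan(r.ppv) and np.isnan(r.specificity)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            confusion_metrics([1, 0], [1], positive_class=1)


class TestRocAuc:
    def test_perfect_separation_and_all_ties(self):
        y = np.array([0] * 5 + [1] * 5)
        *_, auc = roc_auc(np.concatenate([np.zeros(5), np.ones(5)]), y, positive_class=1)
        assert auc == 1.0
        *_, auc_tied = roc_auc(np.full(10, 0.5), y, positive_class=1)
        assert auc_tied == 0.5

    def test_equals_rank_sum_statistic_on_random_instances(self, rng):
        """AUC must equal U/(n1*n0) with midrank tie correction, to 1e-12."""
        from scipy.stats import rankdata

        for _ in range(100):
            n1, n0 = rng.integers(5, 40, 2)
            y = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
            scores = np.round(rng.random(n1 + n0), rng.integers(1, 3))  # force ties
            ranks = rankdata(scores)
            u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            *_, auc = roc_auc(scores, y, positive_class=1)
            assert abs(auc - u / (n1 * n0)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(InvalidDataError):
            roc_auc([0.1, 0.9], [1, 1], positive_class=1)


class TestCohensKappa:
    def test_identical_raters_with_both_classes(self):
        a = np.array([0, 1, 0, 1, 1])
        assert cohens_kappa(a, a) == 1.0

    def test_hand_computed_two_by_two_table(self):
        # agreement table [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        a = np.array([0] * 25 + [1] * 25)
        b = np.array([0] * 20 + [1] * 5 + [0] * 10 + [1] * 15)
        assert cohens_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_independent_raters_near_zero(self, rng):
        n = 10_000
        a, b = rng.integers(0, 2, n), rng.integers(0, 2, n)
        assert abs(cohens_kappa(a, b)) < 3 / np.sqrt(n) * 2

    def test_matches_reference_implementation(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a, b = rng.integers(0, 3, 200), rng.integers(0, 3, 200)
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_constant_equal_raters_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cohens_kappa(np.ones(5), np.ones(5))


class TestTTests:
    def test_identical_samples_give_t0_p1(self):
        t, df, p = unpaired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0) and df == 4

    def test_hand_computed_two_sample(self):
        t, df, p = unpaired_ttest([0.95, 0.96, 0.97], [0.86, 0.87, 0.88])
        assert df == 4
        assert t == pytest.approx(0.09 / (0.01 * np.sqrt(2 / 3)), rel=1e-6)

    def test_swapping_samples_negates_t_preserves_p(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        t1, _, p1 = unpaired_ttest(a, b)
        t2, _, p2 = unpaired_ttest(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_hand_computed_one_sample(self):
        t, df, p = one_sample_ttest([0.94, 0.97, 0.91], 0.75)
        assert df == 2
        s = np.std([0.94, 0.97, 0.91], ddof=1)
        assert t == pytest.approx((0.94 - 0.75) / (s / np.sqrt(3)), rel=1e-6)

    def test_one_sample_p_monotone_in_reference_distance(self):
        sample = [0.5, 0.6, 0.55, 0.52]
        ps = [one_sample_ttest(sample, ref)[2] for ref in np.linspace(0.5425, 0.9, 20)]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_zero_variance_degenerate_handling(self):
        t, _, p = one_sample_ttest([0.5, 0.5, 0.5], 0.5)
        assert (t, p) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            t, _, p = one_sample_ttest([0.5, 0.5, 0.5], 0.7)
        assert np.isinf(t) and p == 0.0


class TestKs:
    def test_identical_and_disjoint_samples(self):
        a = np.zeros(100)
        d, p = ks_compare(a, a)
        assert d == 0.0 and p == pytest.approx(1.0)
        d, _ = ks_compare(np.zeros(100), np.ones(100))
        assert d == 1.0

    def test_small_sample_statistic_matches_ecdf_brute_force(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(size=rng.integers(3, 12))
            grid = np.sort(np.concatenate([a, b]))
            fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
            fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
            d, _ = ks_compare(a, b)
            assert d == pytest.approx(np.abs(fa - fb).max())

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ks_compare([], [1.0])


def _table(n, n_fail):
    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "label_v1": ["failing"] * n_fail + ["non-failing"] * (n - n_fail),
    })


class TestSplits:
    def test_104_patients_three_folds_sizes(self):
        fa = crossval_split(_table(104, 52), n_folds=3, rng_seed=0)
        sizes = sorted(len(fa.patients_in(f)) for f in range(3))
        assert sizes == [34, 35, 35]

    def test_every_patient_in_exactly_one_fold(self):
        t = _table(31, 14)
        fa = crossval_split(t, n_folds=3, rng_seed=1)
        assert sorted(fa.folds) == sorted(t["patient_id"])

    def test_fold_assignment_deterministic(self):
        t = _table(40, 20)
        assert crossval_split(t, 3, rng_seed=5).folds == crossval_split(t, 3, rng_seed=5).folds

    def test_more_folds_than_patients_rejected(self):
        with pytest.raises(InvalidArgumentError):
            crossval_split(_table(2, 1), n_folds=3)

    def test_209_patients_split_104_train_105_test(self):
        train, test = train_test_split_patients(_table(209, 93), rng_seed=0)
        assert len(train) == 104 and len(test) == 105
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(_table(209, 93)["patient_id"])

    def test_stratification_within_one_patient(self):
        t = _table(10, 5)
        train, test = train_test_split_patients(t, rng_seed=2)
        lab = dict(zip(t["patient_id"], t["label_v1"]))
        n_fail_train = sum(lab[p] == "failing" for p in train)
        assert abs(n_fail_train - len(train) / 2) <= 1

    def test_split_deterministic(self):
        t = _table(21, 9)
        assert train_test_split_patients(t, rng_seed=3) == train_test_split_patients(t, rng_seed=3)
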
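"""Metric correctness against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fingertox as ft
from conftest import LinearScoreModel


def brute_force_fpr_at_tpr(scores, labels, tpr_target):
    """Enumerate every threshold in the score set (ties grouped)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    mask = ~np.isnan(y)
    s, y = s[mask], y[mask]
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best = (np.inf, -np.inf)
    for t in np.unique(s):
        pred = s >= t
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        if tpr >= tpr_target and (fpr < best[0] or (fpr == best[0] and t > best[1])):
            best = (fpr, t)
    return best


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_instance(rng, allow_ties=True):
    n = int(rng.integers(8, 30))
    scores = rng.choice(np.linspace(0, 1, 7), size=n) if allow_ties else rng.random(n)
    labels = rng.integers(0, 2, size=n).astype(float)
    if (labels == 1).sum() == 0:
        labels[0] = 1.0
    if (labels == 0).sum() == 0:
        labels[1] = 0.0
    return scores, labels


class TestFprAtTpr:
    def test_perfect_separation_gives_zero_fpr(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1.0, 1.0, 0.0, 0.0])
        assert ft.fpr_at_tpr(scores, labels).fpr == 0.0

    def test_constant_scores_force_fpr_one(self):
        fpr, _ = ft.fpr_at_tpr(np.full(30, 0.5), np.r_[np.ones(10), np.zeros(20)])
        assert fpr == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            scores, labels = random_instance(rng)
            fpr, thr = ft.fpr_at_tpr(scores, labels, 0.9)
            bf_fpr, bf_thr = brute_force_fpr_at_tpr(scores, labels, 0.9)
            assert fpr == pytest.approx(bf_fpr)
            assert thr == pytest.approx(bf_thr)

    def test_monotone_in_tpr_target(self):
        rng = np.random.default_rng(2)
        scores, labels = random_instance(rng)
        fprs = [ft.fpr_at_tpr(scores, labels, t).fpr for t in (0.5, 0.7, 0.9, 1.0)]
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))

    def test_undefined_without_positives(self):
        with pytest.warns(UserWarning, match="positives"):
            result = ft.fpr_at_tpr(np.array([0.1, 0.9]), np.array([0.0, 0.0]))
        assert np.isnan(result.fpr)

    def test_missing_labels_excluded(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1, 0.99])
        labels = np.array([1.0, 1.0, 0.0, 0.0, np.nan])
        assert ft.fpr_at_tpr(scores, labels).fpr == 0.0


class TestRocAuc:
    def test_perfect_and_reversed_ranking(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        assert ft.roc_auc([0.9, 0.8, 0.2, 0.1], y) == 1.0
        assert ft.roc_auc([0.1, 0.2, 0.8, 0.9], y) == 0.0

    def test_matches_pairwise_counting_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            scores, labels = random_instance(rng)
            assert ft.roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng, allow_ties=False)
        base = ft.roc_auc(scores, labels)
        assert ft.roc_auc(np.exp(3 * scores), labels) == pytest.approx(base)
        assert ft.roc_auc(scores**3 + scores, labels) == pytest.approx(base)


class TestBalancedAccuracy:
    def test_all_correct_is_one(self):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        assert ft.balanced_accuracy(np.array([0.9, 0.1, 0.8, 0.2]), y) == 1.0

    def test_hand_confusion_table(self):
        # sensitivity 2/3, specificity 1/2 -> 7/12
        scores = np.array([0.9, 0.8, 0.1, 0.6, 0.4])
        labels = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
        assert ft.balanced_accuracy(scores, labels) == pytest.approx(7 / 12)

    def test_random_scores_near_half_at_large_n(self):
        rng = np.random.default_rng(4)
        scores = rng.random(20_000)
        labels = rng.integers(0, 2, 20_000).astype(float)
        assert ft.balanced_accuracy(scores, labels) == pytest.approx(0.5, abs=0.02)


class TestDisagreementRate:
    def test_identical_and_complementary(self):
        a = np.array([1, 0, 1, 0])
        assert ft.disagreement_rate(a, a) == 0.0
        assert ft.disagreement_rate(a, 1 - a) == 1.0

    def test_counting(self):
        a = np.array([1, 1, 1, 0, 0, 0, 1, 0, 1, 0])
        b = np.array([1, 0, 1, 1, 0, 0, 1, 1, 1, 0])
        assert ft.disagreement_rate(a, b) == pytest.approx(0.3)


class TestAssayCorrelation:
    def test_diagonal_is_one(self, labels_small):
        corr = ft.assay_correlation(labels_small)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_assays_uncorrelated(self):
        fp = ft.generate_fingerprints(10_000, 30, n_blocks=30, rho=0.0, seed=5)
        model = ft.plant_toxicophores(list(fp.columns), 2, 4, 2.0, 0.0, 0.1, fp, seed=6)
        labels = ft.simulate_labels(fp, model, 0.1, seed=7)
        corr = ft.assay_correlation(labels)
        assert abs(corr.iloc[0, 1]) < 0.05

    def test_shared_toxicophores_correlate(self):
        fp = ft.generate_fingerprints(10_000, 30, n_blocks=30, rho=0.0, seed=8)
        model = ft.plant_toxicophores(list(fp.columns), 2, 4, 2.0, 1.0, 0.1, fp, seed=9)
        labels = ft.simulate_labels(fp, model, 0.1, seed=10)
        assert ft.assay_correlation(labels).iloc[0, 1] > 0.1

    def test_sparse_overlap_reported_missing(self):
        labels = pd.DataFrame({"a": [1.0, 0.0, np.nan, np.nan],
                               "b": [np.nan, np.nan, 1.0, 0.0]})
        corr = ft.assay_correlation(labels, min_n=2)
        assert np.isnan(corr.loc["a", "b"])


class TestPermutationImportance:
    def test_causal_feature_ranks_first_and_ignored_feature_drops_nothing(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(
            rng.integers(0, 2, size=(600, 5)).astype(float),
            columns=[f"f{j}" for j in range(5)],
        )
        model = LinearScoreModel(np.array([4.0, 0, 0, 0, 0]), feature_ids=list(X.columns))
        y = (X["f0"] + 0.05 * rng.standard_normal(600) > 0.5).astype(float)
        imp = ft.permutation_importance(model, X, y, n_repeats=5, seed=12)
        assert imp.iloc[0]["feature_id"] == "f0"
        ignored = imp.set_index("feature_id").loc["f3", "mean_drop"]
        assert abs(ignored) < 0.02

    def test_reproducible_per_seed(self, fingerprints_small, labels_small):
        y = labels_small.iloc[:, 0]
        model = LinearScoreModel(
            np.ones(fingerprints_small.shape[1]) / 10,
            feature_ids=list(fingerprints_small.columns),
        )
        a = ft.permutation_importance(model, fingerprints_small, y, n_repeats=3, seed=1)
        b = ft.permutation_importance(model, fingerprints_small, y, n_repeats=3, seed=1)
        pd.testing.assert_frame_equal(a, b)


class TestEvaluationReport:
    def test_report_fields_and_n_evaluated(self, labels_small):
        rng = np.random.default_rng(13)
        scores = pd.DataFrame(
            rng.random(labels_small.shape),
            index=labels_small.index,
            columns=labels_small.columns,
        )
        report = ft.evaluation_report(scores, labels_small)
        per_assay = report.per_assay
        assert set(per_assay.columns) >= {
            "fpr_at_tpr",
            "roc_auc",
            "balanced_accuracy",
            "n_evaluated",
        }
        expected_n = labels_small.notna().sum()
        assert (per_assay["n_evaluated"] == expected_n).all()
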
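"""Calibration and determinism of the synthetic data generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import fingertox as ft
from fingertox.containers import ReliabilitySpec


class TestGenerateFingerprints:
    def test_independent_features_have_uncorrelated_balanced_columns(self):
        table = ft.generate_fingerprints(
            10_000, 20, n_blocks=20, rho=0.0, prevalence_range=(0.5, 0.5), seed=1
        )
        means = table.mean()
        assert ((means >= 0.47) & (means <= 0.53)).all()
        corr = table.corr().to_numpy()
        off_diag = corr[~np.eye(20, dtype=bool)]
        assert np.abs(off_diag).mean() < 0.05

    def test_high_latent_correlation_gives_strongly_correlated_bits(self):
        table = ft.generate_fingerprints(
            5000, 5, n_blocks=1, rho=0.95, prevalence_range=(0.5, 0.5), seed=2
        )
        corr = table.corr().to_numpy()
        off_diag = corr[~np.eye(5, dtype=bool)]
        assert off_diag.min() > 0.5

    def test_cross_block_features_are_independent(self):
        table = ft.generate_fingerprints(
            20_000, 4, n_blocks=2, rho=0.9, prevalence_range=(0.5, 0.5), seed=3
        )
        corr = table.corr()
        # columns 0,1 are block one; 2,3 block two
        assert corr.iloc[0, 1] > 0.5
        assert abs(corr.iloc[0, 2]) < 0.05

    def test_same_seed_reproduces_table(self):
        a = ft.generate_fingerprints(200, 10, n_blocks=2, rho=0.4, seed=7)
        b = ft.generate_fingerprints(200, 10, n_blocks=2, rho=0.4, seed=7)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(ValueError, match="rho"):
            ft.generate_fingerprints(10, 5, rho=rho, seed=0)


class TestPlantToxicophores:
    def test_zero_effect_intercept_matches_logit_closed_form(self, fingerprints_small):
        model = ft.plant_toxicophores(
            list(fingerprints_small.columns),
            n_assays=2,
            sparsity=3,
            effect_size=0.0,
            share_fraction=0.0,
            target_prevalence=0.05,
            fingerprints=fingerprints_small,
            seed=1,
        )
        assert model.intercepts.to_numpy() == pytest.approx(logit(0.05), abs=0.01)

    def test_each_assay_has_exactly_the_configured_sparsity(self, planted_small):
        nonzero = (planted_small.weights != 0).sum(axis=1)
        assert (nonzero == 4).all()

    def test_intercepts_calibrate_prevalence(self, fingerprints_small, planted_small):
        prevalence = planted_small.activation_prob(fingerprints_small).mean()
        assert prevalence.to_numpy() == pytest.approx(0.1, abs=0.002)

    def test_full_sharing_gives_identical_causal_sets_and_positive_phi(self):
        fp = ft.generate_fingerprints(50_000, 40, n_blocks=40, rho=0.0, seed=31)
        model = ft.plant_toxicophores(
            list(fp.columns), 2, 5, 2.0, 1.0, 0.1, fp, seed=32
        )
        sets = [set(model.causal_features(a)) for a in model.assay_ids]
        assert sets[0] == sets[1]
        labels = ft.simulate_labels(fp, model, 0.0, seed=33)
        phi = labels.corr().iloc[0, 1]
        assert phi > 0.1

    def test_label_correlation_nondecreasing_in_share_fraction(self):
        fp = ft.generate_fingerprints(50_000, 40, n_blocks=40, rho=0.0, seed=41)
        phis = []
        for share in (0.0, 0.5, 1.0):
            model = ft.plant_toxicophores(
                list(fp.columns), 2, 5, 2.0, share, 0.1, fp, seed=42
            )
            labels = ft.simulate_labels(fp, model, 0.0, seed=43)
            phis.append(labels.corr().iloc[0, 1])
        assert phis[0] <= phis[1] <= phis[2]
        assert abs(phis[0]) < 0.05  # disjoint toxicophores: uncorrelated assays


class TestSimulateLabels:
    def test_zero_missing_rate_leaves_no_missing_entries(
        self, fingerprints_small, planted_small
    ):
        labels = ft.simulate_labels(fingerprints_small, planted_small, 0.0, seed=5)
        assert not labels.isna().any().any()

    def test_mcar_chemicals_with_any_missing_matches_closed_form(self):
        fp = ft.generate_fingerprints(10_000, 20, seed=51)
        model = ft.plant_toxicophores(
            list(fp.columns), 12, 3, 1.0, 0.0, 0.05, fp, seed=52
        )
        labels = ft.simulate_labels(fp, model, 0.164, seed=53)
        frac = labels.isna().any(axis=1).mean()
        assert frac == pytest.approx(1 - (1 - 0.164) ** 12, abs=0.02)

    def test_observed_active_fraction_matches_target(self):
        fp = ft.generate_fingerprints(10_000, 20, seed=61)
        model = ft.plant_toxicophores(
            list(fp.columns), 2, 3, 1.5, 0.0, 0.05, fp, seed=62
        )
        labels = ft.simulate_labels(fp, model, 0.3, seed=63)
        observed_active = np.nanmean(labels.to_numpy(), axis=0)
        assert observed_active == pytest.approx(0.05, abs=0.01)


class TestInjectDuplicates:
    def test_zero_fraction_is_identity(self, labels_small):
        records = ft.inject_duplicates(labels_small, 0.0, 0.5, seed=1)
        assert len(records) == len(labels_small)
        np.testing.assert_array_equal(
            records.drop(columns="chem_id").to_numpy(), labels_small.to_numpy()
        )

    def test_no_flips_roundtrips_through_deduplication(self, labels_small):
        records = ft.inject_duplicates(labels_small, 0.4, 0.0, seed=2)
        recovered = ft.deduplicate(records)
        pd.testing.assert_frame_equal(
            recovered.loc[labels_small.index], labels_small, check_names=False
        )

    def test_two_copies_each_gives_expected_record_count(self):
        labels = pd.DataFrame(
            np.zeros((1000, 2)), index=[f"c{i}" for i in range(1000)]
        )
        records = ft.inject_duplicates(
            labels, 0.3, 0.1, copies_range=(2, 2), seed=3
        )
        assert len(records) == 1300


class TestProbabilisticFingerprints:
    def test_degenerate_mode_reproduces_bits_exactly(self, fingerprints_small):
        spec = ReliabilitySpec(
            pd.Series(0.0, index=fingerprints_small.columns),
            concentration=float("inf"),
        )
        probs = ft.emulate_probabilistic_fingerprints(fingerprints_small, spec, seed=1)
        np.testing.assert_array_equal(
            probs.to_numpy(), fingerprints_small.to_numpy().astype(float)
        )

    def test_uniform_error_rate_recovered_by_thresholding(self):
        fp = ft.generate_fingerprints(5000, 10, seed=71)
        spec = ReliabilitySpec(pd.Series(0.04, index=fp.columns))
        probs = ft.emulate_probabilistic_fingerprints(fp, spec, seed=72)
        errors = ((probs >= 0.5).astype(int) != fp).mean()
        assert errors.mean() == pytest.approx(0.04, abs=0.01)

    def test_per_feature_heterogeneity(self):
        fp = ft.generate_fingerprints(5000, 5, seed=81)
        rates = pd.Series(0.02, index=fp.columns)
        rates.iloc[0] = 0.12
        probs = ft.emulate_probabilistic_fingerprints(
            fp, ReliabilitySpec(rates), seed=82
        )
        errors = ((probs >= 0.5).astype(int) != fp).mean()
        assert errors.iloc[0] == pytest.approx(0.12, abs=0.02)
        assert errors.iloc[1:].mean() == pytest.approx(0.02, abs=0.01)

    def test_outputs_stay_inside_open_unit_interval(self, fingerprints_small):
        spec = ReliabilitySpec.default(list(fingerprints_small.columns), seed=9)
        probs = ft.emulate_probabilistic_fingerprints(fingerprints_small, spec, seed=10)
        values = probs.to_numpy()
        assert (values > 0).all() and (values < 1).all()

    def test_invalid_error_rate_rejected(self):
        with pytest.raises(ValueError, match="error rates"):
            ReliabilitySpec(pd.Series([0.5, 1.2], index=["a", "b"]))


def test_operations_are_deterministic_per_seed(labels_small):
    records_a = ft.inject_duplicates(labels_small, 0.2, 0.3, seed=5)
    records_b = ft.inject_duplicates(labels_small, 0.2, 0.3, seed=5)
    pd.testing.assert_frame_equal(records_a, records_b)


def test_expected_unreliable_features_arithmetic():
    assert ft.expected_unreliable_features(0.99, 3494) == pytest.approx(34.94)
    with pytest.raises(ValueError):
        ft.expected_unreliable_features(1.2, 100)
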
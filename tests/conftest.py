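import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import fingertox as ft


class LinearScoreModel:
    """Deterministic sigmoid-linear scorer used as a toy classifier in tests."""

    def __init__(self, weights, bias=0.0, feature_ids=None):
        self.w = np.asarray(weights, dtype=float)
        self.b = float(bias)
        self.feature_ids_ = feature_ids

    def score_active(self, X):
        X = np.asarray(X, dtype=float)
        return expit(X @ self.w + self.b)

    score = score_active


@pytest.fixture(scope="session")
def fingerprints_small():
    return ft.generate_fingerprints(600, 30, n_blocks=3, rho=0.3, seed=11)


@pytest.fixture(scope="session")
def planted_small(fingerprints_small):
    return ft.plant_toxicophores(
        list(fingerprints_small.columns),
        n_assays=3,
        sparsity=4,
        effect_size=2.0,
        share_fraction=0.5,
        target_prevalence=0.1,
        fingerprints=fingerprints_small,
        seed=12,
    )


@pytest.fixture(scope="session")
def labels_small(fingerprints_small, planted_small):
    return ft.simulate_labels(fingerprints_small, planted_small, 0.2, seed=13)


@pytest.fixture
def linear_model():
    rng = np.random.default_rng(21)
    return LinearScoreModel(rng.normal(size=8), bias=-0.5)
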
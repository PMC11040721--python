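"""Core in-memory containers.

Tables (fingerprints, posterior probabilities, activity labels) are plain
:class:`pandas.DataFrame` objects indexed by chemical identifier, with one
column per fingerprint feature or bioassay.  Missing activity labels are
``NaN``.  The dataclasses below carry the structured objects that do not fit
a single table: the planted ground-truth model used by the synthetic
generator, the reliability profile of a fingerprint predictor, filter and
partition reports, and Monte Carlo prediction records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantedModel",
    "ReliabilitySpec",
    "FeatureFilterReport",
    "AnticlusterAssignment",
    "MCPrediction",
    "validate_binary_table",
    "validate_prob_table",
    "validate_label_table",
]


def validate_binary_table(table: pd.DataFrame) -> None:
    """Check a binary fingerprint table: entries in {0, 1}, unique columns."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")
    values = table.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("binary fingerprint table contains entries outside {0, 1}")


def validate_prob_table(table: pd.DataFrame) -> None:
    """Check a probabilistic fingerprint table: entries in [0, 1]."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any() or (values < 0).any() or (values > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")


def validate_label_table(table: pd.DataFrame) -> None:
    """Check an activity label table: entries in {0, 1, NaN}."""
    values = table.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if not np.isin(observed, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 (inactive), 1 (active) or NaN (missing)")


@dataclass
class PlantedModel:
    """Ground-truth sparse logistic model behind a synthetic label matrix.

    ``weights`` is an assays x features frame (mostly zero); ``intercepts``
    holds the per-assay bias calibrated so that the mean activation over a
    reference fingerprint table hits the requested active prevalence.
    ``shared_feature_ids`` lists the causal features reused across assays to
    induce inter-assay label correlation.
    """

    weights: pd.DataFrame
    intercepts: pd.Series
    shared_feature_ids: list[str] = field(default_factory=list)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.weights.columns)

    def causal_features(self, assay_id: str) -> list[str]:
        w = self.weights.loc[assay_id]
        return list(w.index[w != 0])

    def linear_score(self, fingerprints: pd.DataFrame) -> pd.DataFrame:
        """Per-assay linear predictor w_a . x + b_a for each chemical."""
        x = fingerprints[self.feature_ids].to_numpy(dtype=float)
        scores = x @ self.weights.to_numpy(dtype=float).T
        scores += self.intercepts.to_numpy(dtype=float)
        return pd.DataFrame(scores, index=fingerprints.index, columns=self.assay_ids)

    def activation_prob(self, fingerprints: pd.DataFrame) -> pd.DataFrame:
        from scipy.special import expit

        return self.linear_score(fingerprints).apply(expit)

    def to_dict(self) -> dict:
        return {
            "assay_ids": self.assay_ids,
            "feature_ids": self.feature_ids,
            "weights": {
                a: {f: float(v) for f, v in row.items() if v != 0}
                for a, row in self.weights.iterrows()
            },
            "intercepts": {a: float(v) for a, v in self.intercepts.items()},
            "shared_feature_ids": list(self.shared_feature_ids),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PlantedModel":
        weights = pd.DataFrame(
            0.0, index=payload["assay_ids"], columns=payload["feature_ids"]
        )
        for assay, row in payload["weights"].items():
            for feature, value in row.items():
                weights.loc[assay, feature] = value
        intercepts = pd.Series(payload["intercepts"], dtype=float).reindex(
            payload["assay_ids"]
        )
        return cls(weights, intercepts, list(payload["shared_feature_ids"]))


@dataclass
class ReliabilitySpec:
    """Per-feature reliability of a probabilistic fingerprint predictor.

    ``error_rates`` gives e_j, the probability that feature j's posterior
    lands on the wrong side of 0.5.  Conditional posterior shapes are Beta
    distributed with shape ``beta_shape`` = (a, b) scaled by ``concentration``
    and mapped into the half-interval matching (concordant) or opposing
    (discordant) the true bit.  ``concentration = inf`` is the degenerate
    noiseless mode in which the posterior equals the target bit exactly.
    """

    error_rates: pd.Series
    beta_shape: tuple[float, float] = (8.0, 2.0)
    concentration: float = 1.0

    def __post_init__(self) -> None:
        e = self.error_rates.to_numpy(dtype=float)
        if (e < 0).any() or (e > 1).any():
            raise ValueError("per-feature error rates must lie in [0, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.error_rates.index)

    @property
    def degenerate(self) -> bool:
        return math.isinf(self.concentration)

    @classmethod
    def default(
        cls,
        feature_ids: list[str],
        base_error_range: tuple[float, float] = (0.01, 0.04),
        hard_fraction: float = 0.05,
        hard_error: float = 0.12,
        seed: int | None = None,
    ) -> "ReliabilitySpec":
        """Mostly reliable features (96-99%) with a tail of hard ones (~12% error)."""
        rng = np.random.default_rng(seed)
        d = len(feature_ids)
        errors = rng.uniform(*base_error_range, size=d)
        n_hard = int(round(hard_fraction * d))
        if n_hard:
            hard_idx = rng.choice(d, size=n_hard, replace=False)
            errors[hard_idx] = hard_error
        return cls(pd.Series(errors, index=feature_ids))


@dataclass
class FeatureFilterReport:
    """Outcome of a feature-filtering pass."""

    removed_near_zero: list[str]
    removed_correlated: list[str]
    surviving: list[str]
    cutoff: float | None = None

    def __post_init__(self) -> None:
        removed = set(self.removed_near_zero) | set(self.removed_correlated)
        if removed & set(self.surviving):
            raise ValueError("removed and surviving feature sets overlap")


@dataclass
class AnticlusterAssignment:
    """Balanced K-group partition maximising within-group diversity."""

    chem_ids: list[str]
    groups: np.ndarray  # group index per chemical, 0..K-1
    n_groups: int
    objective_value: float
    objective_initial: float = float("nan")

    def __post_init__(self) -> None:
        counts = np.bincount(self.groups, minlength=self.n_groups)
        if counts.max() - counts.min() > 1:
            raise ValueError("anticluster group sizes must differ by at most 1")

    def members(self, group: int) -> list[str]:
        ids = np.asarray(self.chem_ids, dtype=object)
        return list(ids[self.groups == group])

    def to_series(self) -> pd.Series:
        return pd.Series(self.groups, index=self.chem_ids, name="group")


@dataclass
class MCPrediction:
    """Monte Carlo activity prediction for one chemical (and one assay)."""

    chem_id: str
    mean_score: float
    n_samples: int
    final_class: int
    class_threshold: float = 0.5
    assay_id: str | None = None
    checkpoints: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_score <= 1.0:
            raise ValueError("mean_score must lie in [0, 1]")
        expected = int(self.mean_score >= self.class_threshold)
        if self.final_class != expected:
            raise ValueError("final_class inconsistent with mean_score and threshold")
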
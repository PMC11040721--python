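"""Synthetic fingerprint/activity data with planted toxicophores.

The generator reproduces the statistical structure a fingerprint-based
bioassay-activity analysis has to cope with:

* correlated binary fingerprint features (latent-Gaussian copula with block
  structure), motivating variance/correlation filtering;
* sparse ground-truth logistic "toxicophore" models per assay, with a
  configurable fraction of causal features shared across assays so that assay
  labels correlate;
* strongly imbalanced per-assay activity (active fractions of a few percent)
  with labels missing completely at random;
* duplicated records with occasionally conflicting labels, exercising the
  deduplication rule;
* posterior-probability fingerprints emulating an MS2-based predictor whose
  per-feature reliability is high (96-99%) except for a tail of hard features
  (~12% error).

Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .containers import PlantedModel, ReliabilitySpec, validate_binary_table

__all__ = [
    "generate_fingerprints",
    "plant_toxicophores",
    "simulate_labels",
    "inject_duplicates",
    "emulate_probabilistic_fingerprints",
    "expected_unreliable_features",
]


def _chem_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"chem_{i:0{width}d}" for i in range(n)]


def _feature_ids(d: int) -> list[str]:
    width = max(3, len(str(d - 1)))
    return [f"fp_{j:0{width}d}" for j in range(d)]


def generate_fingerprints(
    n_chem: int,
    d: int,
    n_blocks: int = 1,
    rho: float = 0.0,
    prevalence_range: tuple[float, float] = (0.1, 0.4),
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a binary fingerprint table with block-correlated features.

    Features are grouped into ``n_blocks`` contiguous blocks.  A latent
    Gaussian ``z = sqrt(rho) * g_block + sqrt(1 - rho) * eps`` is thresholded
    at the normal quantile of each feature's marginal prevalence (drawn
    uniformly from ``prevalence_range``), so features within a block share
    pairwise latent correlation ``rho`` and features in different blocks are
    independent.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho}")
    if n_chem < 2:
        raise ValueError("n_chem must be at least 2")
    if not 1 <= n_blocks <= d:
        raise ValueError("need d >= n_blocks >= 1")
    lo, hi = prevalence_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("prevalence_range must lie within (0, 1)")

    rng = np.random.default_rng(seed)
    block_of = np.array_split(np.arange(d), n_blocks)
    prevalence = rng.uniform(lo, hi, size=d)
    shared = rng.standard_normal((n_chem, n_blocks))
    noise = rng.standard_normal((n_chem, d))

    z = np.empty((n_chem, d))
    for b, cols in enumerate(block_of):
        z[:, cols] = np.sqrt(rho) * shared[:, [b]] + np.sqrt(1.0 - rho) * noise[:, cols]

    bits = (z <= norm.ppf(prevalence)).astype(np.int8)
    table = pd.DataFrame(bits, index=_chem_ids(n_chem), columns=_feature_ids(d))
    validate_binary_table(table)
    return table


def plant_toxicophores(
    feature_ids: list[str],
    n_assays: int,
    sparsity: int,
    effect_size: float,
    share_fraction: float,
    target_prevalence: float | list[float],
    fingerprints: pd.DataFrame,
    seed: int | None = None,
    random_sign: bool = False,
    prevalence_tol: float = 0.002,
) -> PlantedModel:
    """Plant sparse per-assay logistic toxicophore models.

    Each assay receives ``sparsity`` nonzero weights of magnitude
    ``effect_size`` (all positive unless ``random_sign``).  A fraction
    ``share_fraction`` of each assay's causal features comes from one global
    shared pool, inducing positive inter-assay label correlation; the
    remainder are private to the assay (disjoint across assays while features
    last).  The intercept of each assay is found by root bisection so the mean
    activation over ``fingerprints`` matches ``target_prevalence`` within
    ``prevalence_tol``.
    """
    d = len(feature_ids)
    if sparsity > d:
        raise ValueError("sparsity cannot exceed the number of features")
    if not 0.0 <= share_fraction <= 1.0:
        raise ValueError("share_fraction must lie in [0, 1]")
    targets = np.broadcast_to(np.asarray(target_prevalence, dtype=float), (n_assays,))
    if ((targets <= 0) | (targets >= 1)).any():
        raise ValueError("target prevalences must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    assay_ids = [f"assay_{a:02d}" for a in range(n_assays)]
    n_shared = int(round(share_fraction * sparsity))
    n_private = sparsity - n_shared

    order = rng.permutation(d)
    shared_idx = order[:n_shared]
    private_pool = list(order[n_shared:])

    weights = pd.DataFrame(0.0, index=assay_ids, columns=feature_ids)
    x = fingerprints[feature_ids].to_numpy(dtype=float)
    intercepts = {}
    for a, assay in enumerate(assay_ids):
        if n_private * n_assays <= len(private_pool):
            private_idx = private_pool[a * n_private : (a + 1) * n_private]
        else:  # not enough features for disjoint private sets; sample avoiding shared
            private_idx = rng.choice(private_pool, size=n_private, replace=False)
        causal = np.concatenate([shared_idx, private_idx]).astype(int)
        signs = rng.choice((-1.0, 1.0), size=sparsity) if random_sign else 1.0
        w = np.zeros(d)
        w[causal] = effect_size * signs
        weights.iloc[a] = w

        scores = x @ w
        target = targets[a]

        def gap(b: float) -> float:
            return float(expit(scores + b).mean() - target)

        lo_b, hi_b = -40.0, 40.0
        if gap(lo_b) > 0 or gap(hi_b) < 0:
            raise ValueError(
                f"cannot bracket the intercept for assay {assay!r}: "
                f"target prevalence {target} unreachable with the planted weights"
            )
        intercepts[assay] = brentq(gap, lo_b, hi_b, xtol=1e-10)
        assert abs(gap(intercepts[assay])) <= prevalence_tol

    model = PlantedModel(
        weights=weights,
        intercepts=pd.Series(intercepts, dtype=float),
        shared_feature_ids=[feature_ids[j] for j in shared_idx],
    )
    return model


def simulate_labels(
    fingerprints: pd.DataFrame,
    model: PlantedModel,
    missing_rate: float | list[float] = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw Bernoulli activity labels from a planted model, then mask MCAR.

    Returns a chemicals x assays frame over {1.0, 0.0, NaN}.
    """
    missing = set(model.feature_ids) - set(fingerprints.columns)
    if missing:
        raise ValueError(f"fingerprint table lacks model features: {sorted(missing)}")
    rates = np.broadcast_to(
        np.asarray(missing_rate, dtype=float), (len(model.assay_ids),)
    )
    if ((rates < 0) | (rates >= 1)).any():
        raise ValueError("missing rates must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    probs = model.activation_prob(fingerprints).to_numpy()
    y = (rng.random(probs.shape) < probs).astype(float)
    mask = rng.random(probs.shape) < rates
    y[mask] = np.nan
    return pd.DataFrame(y, index=fingerprints.index, columns=model.assay_ids)


def inject_duplicates(
    labels: pd.DataFrame,
    dup_fraction: float = 0.0,
    flip_prob: float = 0.0,
    copies_range: tuple[int, int] = (2, 3),
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit a raw record table in which some chemicals appear 2-3 times.

    The original record of every chemical is kept verbatim; each selected
    chemical additionally contributes 1-2 duplicate records whose observed
    labels are independently flipped with probability ``flip_prob`` (missing
    labels stay missing).  ``chem_id`` is an ordinary column so downstream
    deduplication can be verified against the input table.
    """
    if not 0.0 <= dup_fraction <= 1.0:
        raise ValueError("dup_fraction must lie in [0, 1]")
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must lie in [0, 1]")
    lo, hi = copies_range
    if not 1 <= lo <= hi:
        raise ValueError("copies_range must satisfy 1 <= lo <= hi")

    rng = np.random.default_rng(seed)
    n = len(labels)
    n_dup = int(round(dup_fraction * n))
    dup_rows = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)

    rows = []
    values = labels.to_numpy(dtype=float)
    dup_set = set(dup_rows.tolist())
    for i, chem in enumerate(labels.index):
        rows.append((chem, values[i]))
        if i in dup_set:
            total_copies = int(rng.integers(lo, hi + 1))
            for _ in range(total_copies - 1):
                dup = values[i].copy()
                observed = ~np.isnan(dup)
                flips = rng.random(dup.shape) < flip_prob
                dup[observed & flips] = 1.0 - dup[observed & flips]
                rows.append((chem, dup))

    records = pd.DataFrame(
        [r[1] for r in rows], columns=list(labels.columns), dtype=float
    )
    records.insert(0, "chem_id", [r[0] for r in rows])
    return records


def emulate_probabilistic_fingerprints(
    bits: pd.DataFrame,
    spec: ReliabilitySpec,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emulate posterior-probability fingerprints for known binary bits.

    For each entry the emitted posterior is concordant with the true bit with
    probability ``1 - e_j`` and discordant with probability ``e_j``.  A Beta
    draw ``B`` with shape ``spec.beta_shape`` (scaled by ``spec.concentration``)
    is mapped onto the target side of 0.5: posterior ``0.5 + 0.5 * B`` when the
    target bit is 1 and ``0.5 * (1 - B)`` when it is 0.  Thresholding at 0.5
    therefore recovers the true bit with per-feature accuracy exactly
    ``1 - e_j`` in expectation.  In the degenerate mode
    (``concentration = inf``) the posterior equals the target bit itself.
    """
    missing = set(bits.columns) - set(spec.feature_ids)
    if missing:
        raise ValueError(f"reliability spec lacks features: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    x = bits.to_numpy(dtype=np.int8)
    e = spec.error_rates.reindex(bits.columns).to_numpy(dtype=float)
    discordant = rng.random(x.shape) < e
    target = np.where(discordant, 1 - x, x)

    if spec.degenerate:
        probs = target.astype(float)
    else:
        a, b = spec.beta_shape
        kappa = spec.concentration
        draw = rng.beta(a * kappa, b * kappa, size=x.shape)
        probs = np.where(target == 1, 0.5 + 0.5 * draw, 0.5 * (1.0 - draw))

    return pd.DataFrame(probs, index=bits.index, columns=bits.columns)


def expected_unreliable_features(accuracy: float, n_features: int) -> float:
    """Expected count of misassigned features at a given per-feature accuracy.

    E.g. a predictor that is right 99% of the time over 3494 features is still
    expected to get ~35 of them wrong for any one chemical.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    return (1.0 - accuracy) * n_features


def logit_prevalence(prevalence: float) -> float:
    """Closed-form intercept for a covariate-free planted assay."""
    return float(logit(prevalence))
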
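"""Monte Carlo consumption of probabilistic fingerprints.

Classifiers here are trained on exact binary fingerprints, but an unidentified
chemical observed by mass spectrometry only offers posterior probabilities
p_j that each structural pattern is present.  Instead of thresholding those
posteriors once (the naive approach), the Monte Carlo strategy draws N binary
fingerprint vectors with independent Bernoulli(p_j) entries, scores each with
the binary-trained model, and averages the N scores into the final activity
prediction.  For small feature sets the exact expectation over all 2^d
completions serves as an enumeration oracle for the estimator.

Sampling uses common random numbers across checkpoint sizes (the first k rows
of an N-sample stream are exactly the k-sample stream for the same seed), so
convergence curves over an N-grid are prefix-consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MCPrediction

__all__ = [
    "sample_binary_vectors",
    "MonteCarloPredictor",
    "predict_monte_carlo",
    "brute_force_expectation",
    "predict_naive",
    "convergence_analysis",
]


def _model_features(model, p: pd.Series | np.ndarray) -> tuple[np.ndarray, list | None]:
    """Probabilities restricted to the features the model consumes."""
    feature_ids = getattr(model, "feature_ids_", None)
    if isinstance(p, pd.Series) and feature_ids is not None:
        missing = [f for f in feature_ids if f not in p.index]
        if missing:
            raise ValueError(f"probability vector lacks model features: {missing}")
        return p[feature_ids].to_numpy(dtype=float), feature_ids
    return np.asarray(p, dtype=float), feature_ids


def sample_binary_vectors(
    p: np.ndarray | pd.Series, n: int, seed: int | None = None
) -> np.ndarray:
    """Draw ``n`` binary vectors with independent Bernoulli(p_j) entries."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((n, p.size)) < p).astype(np.int8)


def _score_matrix(model, X: np.ndarray) -> np.ndarray:
    """Model scores for a sample matrix; shape (n,) or (n, n_assays)."""
    return np.asarray(model.score_active(X), dtype=float)


class MonteCarloPredictor:
    """Monte Carlo activity predictions from probabilistic fingerprints.

    Parameters
    ----------
    model : fitted single- or multi-output classifier with ``score_active``.
    n_samples : int, default 10000
        Number N of Bernoulli fingerprint draws per chemical.
    class_threshold : float, default 0.5
        ``mean_score >= class_threshold`` maps to the active class.
    checkpoints : sequence of int, optional
        Running-mean checkpoints (prefix sizes) recorded per prediction.
    """

    def __init__(
        self,
        model,
        n_samples: int = 10_000,
        class_threshold: float = 0.5,
        checkpoints: tuple[int, ...] = (),
    ):
        if any(c > n_samples or c < 1 for c in checkpoints):
            raise ValueError("checkpoints must lie in [1, n_samples]")
        self.model = model
        self.n_samples = n_samples
        self.class_threshold = class_threshold
        self.checkpoints = tuple(sorted(checkpoints))

    def predict_one(
        self, p: pd.Series | np.ndarray, seed: int | None = None, chem_id: str = ""
    ) -> MCPrediction | list[MCPrediction]:
        probs, _ = _model_features(self.model, p)
        degenerate = bool(np.isin(probs, (0.0, 1.0)).all())
        if degenerate:
            # every sample is the same vector: the MC mean is one exact score
            scores = _score_matrix(self.model, probs.astype(np.int8)[None, :])
        else:
            samples = sample_binary_vectors(probs, self.n_samples, seed=seed)
            scores = _score_matrix(self.model, samples)
        single_output = scores.ndim == 1
        streams = scores[:, None] if single_output else scores

        def summarise(score_stream: np.ndarray, assay_id=None) -> MCPrediction:
            if degenerate:
                mean = float(score_stream[0])
                running = {c: mean for c in self.checkpoints}
            else:
                cumsum = np.cumsum(score_stream)
                running = {c: float(cumsum[c - 1] / c) for c in self.checkpoints}
                mean = float(cumsum[-1] / self.n_samples)
            return MCPrediction(
                chem_id=chem_id,
                assay_id=assay_id,
                mean_score=mean,
                n_samples=self.n_samples,
                final_class=int(mean >= self.class_threshold),
                class_threshold=self.class_threshold,
                checkpoints=running,
            )

        if single_output:
            return summarise(streams[:, 0])
        assay_ids = getattr(self.model, "assay_ids_", range(streams.shape[1]))
        return [
            summarise(streams[:, a], assay_id=aid) for a, aid in enumerate(assay_ids)
        ]

    def predict_table(
        self, prob_table: pd.DataFrame, seed: int | None = None
    ) -> pd.DataFrame:
        """Predictions for every row of a probabilistic fingerprint table.

        Returns a tidy frame (chem_id, assay_id, mean_score, n_samples,
        final_class); per-chemical seeds are derived from ``seed`` by row
        position so single-row and batch calls agree.
        """
        rows = []
        for i, (chem_id, p) in enumerate(prob_table.iterrows()):
            child = None if seed is None else (seed + i) % (2**31)
            preds = self.predict_one(p, seed=child, chem_id=str(chem_id))
            for pred in preds if isinstance(preds, list) else [preds]:
                rows.append(
                    {
                        "chem_id": pred.chem_id,
                        "assay_id": pred.assay_id if pred.assay_id is not None else "score",
                        "mean_score": pred.mean_score,
                        "n_samples": pred.n_samples,
                        "final_class": pred.final_class,
                    }
                )
        return pd.DataFrame(rows)


def predict_monte_carlo(
    model,
    p: pd.Series | np.ndarray,
    n: int = 10_000,
    class_threshold: float = 0.5,
    seed: int | None = None,
    checkpoints: tuple[int, ...] = (),
    chem_id: str = "",
):
    """Single-chemical Monte Carlo prediction (see MonteCarloPredictor)."""
    predictor = MonteCarloPredictor(
        model, n_samples=n, class_threshold=class_threshold, checkpoints=checkpoints
    )
    return predictor.predict_one(p, seed=seed, chem_id=chem_id)


def brute_force_expectation(model, p: pd.Series | np.ndarray, max_uncertain: int = 20):
    """Exact expectation of the model score under independent Bernoulli(p_j).

    Enumerates all 2^d completions over the features with 0 < p_j < 1
    (features at exactly 0 or 1 are forced) and sums score * probability.
    Refuses above ``max_uncertain`` uncertain features; use the Monte Carlo
    estimator there instead.
    """
    probs, _ = _model_features(model, p)
    if np.isnan(probs).any() or (probs < 0).any() or (probs > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    uncertain = np.flatnonzero((probs > 0) & (probs < 1))
    d = len(uncertain)
    if d > max_uncertain:
        raise ValueError(
            f"{d} uncertain features exceed the enumeration limit "
            f"({max_uncertain}); use predict_monte_carlo for larger vectors"
        )
    base = np.round(probs).astype(np.int8)
    n_comb = 2**d
    X = np.tile(base, (n_comb, 1))
    if d:
        combos = (
            (np.arange(n_comb)[:, None] >> np.arange(d)[None, :]) & 1
        ).astype(np.int8)
        X[:, uncertain] = combos
        p_u = probs[uncertain]
        weights = np.prod(
            np.where(combos == 1, p_u, 1.0 - p_u), axis=1
        )
    else:
        weights = np.ones(1)
    scores = _score_matrix(model, X)
    if scores.ndim == 1:
        return float(weights @ scores)
    return weights @ scores  # per-assay expectations


def predict_naive(
    model,
    p: pd.Series | np.ndarray,
    feature_threshold: float = 0.5,
    class_threshold: float = 0.5,
):
    """Naive baseline: binarise p at ``feature_threshold`` (>= is present),
    score once.  Returns (score, class); arrays per assay for multi-output."""
    probs, _ = _model_features(model, p)
    x = (probs >= feature_threshold).astype(np.int8)
    scores = _score_matrix(model, x[None, :])[0]
    if np.ndim(scores) == 0:
        return float(scores), int(scores >= class_threshold)
    return np.asarray(scores), (np.asarray(scores) >= class_threshold).astype(int)


def convergence_analysis(
    model,
    prob_table: pd.DataFrame,
    n_grid: tuple[int, ...],
    class_threshold: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Class stability of the MC prediction across sampling depths.

    For every chemical (and assay), the thresholded class is computed at each
    N in the sorted grid using one shared sample stream (prefix reuse, so all
    checkpoints are mutually consistent).  A chemical is ``flipped`` when its
    class at any smaller N differs from its class at max(N).
    """
    n_grid = tuple(sorted(n_grid))
    predictor = MonteCarloPredictor(
        model,
        n_samples=n_grid[-1],
        class_threshold=class_threshold,
        checkpoints=n_grid,
    )
    rows = []
    for i, (chem_id, p) in enumerate(prob_table.iterrows()):
        child = None if seed is None else (seed + i) % (2**31)
        preds = predictor.predict_one(p, seed=child, chem_id=str(chem_id))
        for pred in preds if isinstance(preds, list) else [preds]:
            classes = {
                n: int(pred.checkpoints[n] >= class_threshold) for n in n_grid
            }
            final = classes[n_grid[-1]]
            row = {
                "chem_id": pred.chem_id,
                "assay_id": pred.assay_id if pred.assay_id is not None else "score",
                "flipped": any(classes[n] != final for n in n_grid),
            }
            row.update({f"mean_at_{n}": pred.checkpoints[n] for n in n_grid})
            row.update({f"class_at_{n}": classes[n] for n in n_grid})
            rows.append(row)
    return pd.DataFrame(rows)
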
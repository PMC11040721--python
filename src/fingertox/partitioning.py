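"""Anticlustering partitions, CV folds and stratified subsetting.

Anticlustering is the mirror image of clustering: items are divided into K
balanced groups that are as *similar to each other* as possible, by maximising
the diversity objective (the sum over groups of within-group pairwise
distances).  Groups produced this way make representative train/test splits
and CV folds for data with heavy class imbalance and many missing labels.

The search is the standard pairwise-exchange heuristic: starting from a
random balanced assignment, repeatedly swap two items in different groups
whenever the swap increases the objective, sweeping until no improving swap
exists or ``max_sweeps`` is reached.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import AnticlusterAssignment

__all__ = [
    "Anticlustering",
    "anticluster",
    "balanced_group_sizes",
    "encode_labels",
    "split_train_test",
    "make_cv_folds",
    "stratified_subset",
    "target_cell_counts",
    "subset_size",
]


def balanced_group_sizes(n: int, k: int) -> np.ndarray:
    """Group sizes differing by at most 1; the remainder goes to the lowest
    group indices."""
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= K <= n, got K={k}, n={n}")
    base, rem = divmod(n, k)
    return np.array([base + (g < rem) for g in range(k)], dtype=int)


class Anticlustering(BaseEstimator, ClusterMixin):
    """Balanced K-group anticlustering by pairwise exchange.

    Parameters
    ----------
    n_groups : int
        Number of groups K.
    max_sweeps : int, default 20
        Maximum full passes of the exchange search.
    n_init : int, default 1
        Independent restarts of the exchange search; the assignment with the
        best diversity objective wins.  The exchange heuristic can stall in a
        swap-local optimum, and restarting it is the usual remedy on small
        problems.
    metric : str, default "sqeuclidean"
        Distance metric handed to :func:`scipy.spatial.distance.pdist`.
    random_state : int or None
        Seed for the balanced random initialisation and sweep order.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Group index per item.
    objective_value_ : float
        Diversity objective (sum of within-group pairwise distances).
    objective_initial_ : float
        Objective of the initial random balanced assignment.
    n_sweeps_ : int
        Sweeps actually performed.
    """

    def __init__(
        self,
        n_groups: int = 5,
        max_sweeps: int = 20,
        n_init: int = 1,
        metric: str = "sqeuclidean",
        random_state: int | None = None,
    ):
        self.n_groups = n_groups
        self.max_sweeps = max_sweeps
        self.n_init = n_init
        self.metric = metric
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        # float32 distances keep memory manageable on large problems
        dtype = np.float64 if n <= 4000 else np.float32
        dist = squareform(pdist(X, metric=self.metric)).astype(dtype)
        rng = np.random.default_rng(self.random_state)

        best = None
        for _ in range(max(1, self.n_init)):
            result = self._exchange_once(dist, rng)
            if best is None or result[1] > best[1]:
                best = result
        self.labels_, self.objective_value_, self.objective_initial_, self.n_sweeps_ = (
            best
        )
        return self

    def _exchange_once(self, dist, rng):
        n, k = dist.shape[0], self.n_groups
        sizes = balanced_group_sizes(n, k)
        labels = np.repeat(np.arange(k), sizes)
        rng.shuffle(labels)
        onehot = np.zeros((n, k), dtype=dist.dtype)
        onehot[np.arange(n), labels] = 1.0
        group_sums = dist @ onehot  # item-to-group distance sums, n x K

        def full_objective(lab):
            return sum(
                float(dist[np.ix_(lab == g, lab == g)].sum(dtype=np.float64)) / 2.0
                for g in range(k)
            )

        objective = full_objective(labels)
        objective_initial = objective

        eps = 1e-9
        sweeps = 0
        for sweeps in range(1, self.max_sweeps + 1):
            improved = False
            order = rng.permutation(n)
            for i in order:
                a = labels[i]
                # swap gain for exchanging i with every item j in another group
                delta = (
                    group_sums[i, labels]
                    + group_sums[:, a]
                    - group_sums[i, a]
                    - group_sums[np.arange(n), labels]
                    - 2.0 * dist[i]
                )
                delta[labels == a] = -np.inf
                j = int(np.argmax(delta))
                if delta[j] > eps:
                    b = labels[j]
                    assert delta[j] > 0.0  # exchange never decreases the objective
                    labels[i], labels[j] = b, a
                    group_sums[:, a] += dist[:, j] - dist[:, i]
                    group_sums[:, b] += dist[:, i] - dist[:, j]
                    objective += float(delta[j])
                    improved = True
            if not improved:
                break

        return labels, full_objective(labels), objective_initial, sweeps

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def anticluster(
    data: pd.DataFrame | np.ndarray,
    k: int,
    max_sweeps: int = 20,
    seed: int | None = None,
    n_init: int = 1,
    metric: str = "sqeuclidean",
) -> AnticlusterAssignment:
    if isinstance(data, pd.DataFrame):
        chem_ids = list(data.index)
        matrix = data.to_numpy(dtype=float)
    else:
        matrix = np.asarray(data, dtype=float)
        chem_ids = [str(i) for i in range(matrix.shape[0])]
    est = Anticlustering(
        n_groups=k, max_sweeps=max_sweeps, n_init=n_init, metric=metric,
        random_state=seed,
    ).fit(matrix)
    return AnticlusterAssignment(
        chem_ids=chem_ids,
        groups=est.labels_,
        n_groups=k,
        objective_value=est.objective_value_,
        objective_initial=est.objective_initial_,
    )


def encode_labels(labels: pd.DataFrame, missing_value: float = 0.5) -> pd.DataFrame:
    """Numeric encoding for distance computations: active 1, inactive 0,
    missing ``missing_value`` (midway by default)."""
    return labels.fillna(missing_value)


def split_train_test(
    labels: pd.DataFrame,
    k: int = 5,
    seed: int | None = None,
    max_sweeps: int = 20,
    features: pd.DataFrame | None = None,
) -> tuple[list[str], list[str]]:
    """Anticluster chemicals into K groups on their (encoded) label profiles
    and hold one uniformly chosen group out as the test set (1/K fraction).

    ``features`` may augment the label encoding (label-only by default).
    """
    encoded = encode_labels(labels)
    if features is not None:
        encoded = pd.concat([encoded, features.loc[encoded.index]], axis=1)
    assignment = anticluster(encoded, k=k, max_sweeps=max_sweeps, seed=seed)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    test_group = int(rng.integers(k))
    test_ids = assignment.members(test_group)
    train_ids = [c for c in labels.index if c not in set(test_ids)]
    return train_ids, test_ids


def make_cv_folds(
    labels: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
    max_sweeps: int = 20,
    features: pd.DataFrame | None = None,
) -> pd.Series:
    """Anticlustered cross-validation folds: fold index per chemical."""
    encoded = encode_labels(labels)
    if features is not None:
        encoded = pd.concat([encoded, features.loc[encoded.index]], axis=1)
    assignment = anticluster(encoded, k=k, max_sweeps=max_sweeps, seed=seed)
    return pd.Series(assignment.groups, index=labels.index, name="fold")


def subset_size(n: int, fraction: float) -> int:
    """Round-half-away-from-zero of fraction * n."""
    x = fraction * n
    return int(np.floor(x + 0.5))


def target_cell_counts(proportions: np.ndarray | list[float], size: int) -> np.ndarray:
    """Per-cell target counts: round(proportion * size) for each cell."""
    p = np.asarray(proportions, dtype=float)
    return np.floor(p * size + 0.5).astype(int)


def stratified_subset(
    labels: pd.DataFrame,
    fraction: float,
    tolerance: int = 5,
    max_tries: int = 1000,
    seed: int | None = None,
    eligible: pd.Series | None = None,
) -> list[str]:
    """Proportion-matching subset by repeated random sampling.

    Draws subsets of size round(fraction * n) from the eligible pool until,
    for every assay, the subset's active/inactive/missing counts are each
    within ``tolerance`` of round(full-data proportion * subset size).
    Returns the first success; if ``max_tries`` is exhausted the best-scoring
    attempt is returned with a warning.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(labels)
    size = subset_size(n, fraction)
    pool = labels.index if eligible is None else labels.index[eligible.loc[labels.index]]
    if len(pool) < size:
        raise ValueError(f"eligible pool ({len(pool)}) smaller than subset size {size}")

    values = labels.to_numpy(dtype=float)
    full_counts = np.stack(
        [
            np.nansum(values == 1.0, axis=0),
            np.nansum(values == 0.0, axis=0),
            np.isnan(values).sum(axis=0),
        ]
    )  # 3 x assays
    targets = target_cell_counts(full_counts / n, size)

    rng = np.random.default_rng(seed)
    pool_positions = labels.index.get_indexer(pool)
    best_ids, best_score = None, np.inf
    for _ in range(max_tries):
        pick = rng.choice(pool_positions, size=size, replace=False)
        sub = values[pick]
        counts = np.stack(
            [
                np.nansum(sub == 1.0, axis=0),
                np.nansum(sub == 0.0, axis=0),
                np.isnan(sub).sum(axis=0),
            ]
        )
        dev = np.abs(counts - targets)
        if dev.max() <= tolerance:
            return list(labels.index[np.sort(pick)])
        score = dev.max()
        if score < best_score:
            best_score, best_ids = score, pick
    warnings.warn(
        f"stratified_subset: no draw met tolerance {tolerance} in {max_tries} tries; "
        f"returning best attempt (max cell deviation {best_score:.0f})"
    )
    return list(labels.index[np.sort(best_ids)])
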
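"""Classifiers for imbalanced multi-assay activity data.

Two model families share one scoring contract (a probability of activity per
chemical, per assay):

* :class:`ToxicityClassifier` — a single-output classifier (logistic
  regression, random forest or gradient boosting) selected by grid search
  with externally supplied CV folds and mean out-of-fold ROC-AUC, optionally
  preceded by down-/up-/SMOTE resampling of the training portion of each fold.
* :class:`MaskedMLPClassifier` — a multi-output feed-forward network with one
  sigmoid output per assay, trained by Adam on a binary cross-entropy that
  skips missing labels entirely (zero loss and zero gradient at missing
  cells).  Implemented as a compact numpy MLP: ReLU hidden layers, inverted
  dropout, L2 weight decay, optional batch normalisation, and early stopping
  on a masked validation loss.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "resample_balance",
    "ToxicityClassifier",
    "train_single_output",
    "masked_bce",
    "masked_bce_grad",
    "MaskedMLPClassifier",
    "train_multi_output",
    "predict_scores",
]


# ---------------------------------------------------------------------------
# resampling


def resample_balance(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    k_neighbors: int = 5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary training set by down-, up- or SMOTE resampling.

    ``down`` subsamples the majority class without replacement to the minority
    size; ``up`` resamples the minority with replacement to the majority size;
    ``smote`` adds synthetic minority points ``x_i + u * (x_nn - x_i)`` with
    ``u ~ U(0, 1)`` and ``x_nn`` one of the ``k_neighbors`` nearest minority
    neighbours of ``x_i``.  SMOTE outputs are left continuous.  Majority rows
    are never fabricated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("resampling requires both classes to be present")
    minority, majority = classes[np.argmin(counts)], classes[np.argmax(counts)]
    if counts[0] == counts[1]:
        minority, majority = classes[0], classes[1]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    rng = np.random.default_rng(seed)

    if method == "down":
        keep = rng.choice(maj_idx, size=len(min_idx), replace=False)
        idx = np.concatenate([min_idx, keep])
        return X[idx], y[idx]
    if method == "up":
        extra = rng.choice(min_idx, size=len(maj_idx) - len(min_idx), replace=True)
        idx = np.concatenate([np.arange(len(y)), extra])
        return X[idx], y[idx]
    if method == "smote":
        n_new = len(maj_idx) - len(min_idx)
        if n_new == 0:
            return X.copy(), y.copy()
        X_min = X[min_idx]
        k = k_neighbors
        if len(min_idx) <= k:
            k = len(min_idx) - 1
            warnings.warn(
                f"SMOTE: minority size {len(min_idx)} <= k_neighbors; using k={k}"
            )
        if k < 1:
            warnings.warn("SMOTE: single minority point; duplicating it instead")
            synth = np.repeat(X_min, n_new, axis=0)
        else:
            nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
            neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
            base = rng.integers(len(min_idx), size=n_new)
            pick = neigh[base, rng.integers(k, size=n_new)]
            u = rng.random((n_new, 1))
            synth = X_min[base] + u * (X_min[pick] - X_min[base])
        X_out = np.vstack([X, synth])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out
    raise ValueError(f"unknown resampling method: {method!r}")


# ---------------------------------------------------------------------------
# single-output classifiers


def _base_estimator(algorithm: str, random_state: int | None):
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000, random_state=random_state)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=random_state, n_jobs=1)
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=random_state)
    raise ValueError(f"unknown algorithm: {algorithm!r}")


class ToxicityClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched single-assay activity classifier.

    Parameters
    ----------
    algorithm : {"logistic", "random_forest", "gradient_boosting"}
    grid : dict of parameter lists, optional
        Hyperparameter grid; the first point (in :class:`ParameterGrid`
        order) wins ties.  ``None`` means the estimator's defaults.
    resample : {None, "down", "up", "smote"}
        Resampling applied to the training portion of every fold and to the
        final refit — never to validation data.
    k_neighbors : int
        SMOTE neighbour count.
    random_state : int or None

    Attributes
    ----------
    best_params_, best_score_ : chosen grid point and its mean fold ROC-AUC.
    cv_results_ : list of (params, mean ROC-AUC, per-fold ROC-AUC).
    estimator_ : the refitted scikit-learn estimator.
    feature_ids_ : feature names consumed (when fitted on a DataFrame).
    """

    def __init__(
        self,
        algorithm: str = "random_forest",
        grid: dict | None = None,
        resample: str | None = None,
        k_neighbors: int = 5,
        random_state: int | None = None,
    ):
        self.algorithm = algorithm
        self.grid = grid
        self.resample = resample
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def _resample(self, X, y, seed):
        if self.resample is None:
            return X, y
        return resample_balance(
            X, y, self.resample, k_neighbors=self.k_neighbors, seed=seed
        )

    def fit(self, X, y, folds=None):
        if isinstance(X, pd.DataFrame):
            self.feature_ids_ = list(X.columns)
            X_arr = X.to_numpy(dtype=float)
        else:
            X_arr = np.asarray(X, dtype=float)
            self.feature_ids_ = None
        y_arr = np.asarray(y, dtype=float)

        observed = ~np.isnan(y_arr)
        X_arr, y_arr = X_arr[observed], y_arr[observed].astype(int)
        if folds is not None:
            folds = np.asarray(folds)[observed]
        if len(np.unique(y_arr)) < 2:
            raise ValueError("need both classes among the observed labels")

        if self.grid is not None and len(self.grid) == 0 and self.grid != {}:
            raise ValueError("empty hyperparameter grid")
        if isinstance(self.grid, (list, tuple)) and len(self.grid) == 0:
            raise ValueError("empty hyperparameter grid")
        grid_points = list(ParameterGrid(self.grid or {}))

        if folds is None:
            skf = StratifiedKFold(
                n_splits=10, shuffle=True, random_state=self.random_state
            )
            folds = np.empty(len(y_arr), dtype=int)
            for f, (_, val) in enumerate(skf.split(X_arr, y_arr)):
                folds[val] = f
        fold_ids = np.unique(folds)

        self.cv_results_ = []
        for params in grid_points:
            fold_scores = []
            for f in fold_ids:
                tr, va = folds != f, folds == f
                if len(np.unique(y_arr[va])) < 2 or len(np.unique(y_arr[tr])) < 2:
                    fold_scores.append(np.nan)
                    continue
                X_tr, y_tr = self._resample(
                    X_arr[tr], y_arr[tr], seed=self.random_state
                )
                est = clone(_base_estimator(self.algorithm, self.random_state))
                est.set_params(**params)
                est.fit(X_tr, y_tr)
                scores = est.predict_proba(X_arr[va])[:, list(est.classes_).index(1)]
                fold_scores.append(roc_auc_score(y_arr[va], scores))
            mean_score = float(np.nanmean(fold_scores))
            self.cv_results_.append((params, mean_score, fold_scores))

        best = int(np.argmax([r[1] for r in self.cv_results_]))  # first wins ties
        self.best_params_ = self.cv_results_[best][0]
        self.best_score_ = self.cv_results_[best][1]

        X_fit, y_fit = self._resample(X_arr, y_arr, seed=self.random_state)
        est = clone(_base_estimator(self.algorithm, self.random_state))
        est.set_params(**self.best_params_)
        self.estimator_ = est.fit(X_fit, y_fit)
        self.classes_ = np.array([0, 1])
        return self

    def _align(self, X):
        if isinstance(X, pd.DataFrame) and self.feature_ids_ is not None:
            missing = [f for f in self.feature_ids_ if f not in X.columns]
            if missing:
                raise ValueError(f"missing required feature columns: {missing}")
            return X[self.feature_ids_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def score_active(self, X) -> np.ndarray:
        """Probability of the active class for each row."""
        check_is_fitted(self, "estimator_")
        proba = self.estimator_.predict_proba(self._align(X))
        return proba[:, list(self.estimator_.classes_).index(1)]

    # spec scoring contract
    score = score_active

    def predict_proba(self, X) -> np.ndarray:
        p = self.score_active(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.score_active(X) >= 0.5).astype(int)


def train_single_output(
    X,
    y,
    algorithm: str = "random_forest",
    grid: dict | None = None,
    folds=None,
    resample: str | None = None,
    k_neighbors: int = 5,
    random_state: int | None = None,
) -> ToxicityClassifier:
    """Fit a grid-searched single-output classifier (see ToxicityClassifier)."""
    clf = ToxicityClassifier(
        algorithm=algorithm,
        grid=grid,
        resample=resample,
        k_neighbors=k_neighbors,
        random_state=random_state,
    )
    return clf.fit(X, y, folds=folds)


# ---------------------------------------------------------------------------
# masked multi-label loss


def masked_bce(predictions, labels) -> float:
    """Mean binary cross-entropy over observed label cells only.

    ``L = -(1/M) sum_observed [y log p + (1-y) log(1-p)]`` with M the number
    of observed (non-missing) cells.  Missing cells contribute neither loss
    nor gradient.  M = 0 is defined as 0 with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    mask = ~np.isnan(y)
    m = int(mask.sum())
    if m == 0:
        warnings.warn("masked_bce: no observed labels; loss defined as 0")
        return 0.0
    p_obs, y_obs = p[mask], y[mask]
    return float(-(y_obs * np.log(p_obs) + (1 - y_obs) * np.log(1 - p_obs)).sum() / m)


def masked_bce_grad(predictions, labels) -> np.ndarray:
    """Gradient of :func:`masked_bce` w.r.t. the predictions.

    Exactly zero at missing cells.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    mask = ~np.isnan(y)
    m = int(mask.sum())
    grad = np.zeros_like(p)
    if m == 0:
        return grad
    grad[mask] = -(y[mask] / p[mask] - (1 - y[mask]) / (1 - p[mask])) / m
    return grad


# ---------------------------------------------------------------------------
# multi-output network


class MaskedMLPClassifier(BaseEstimator, ClassifierMixin):
    """Multi-assay feed-forward network with a missing-label-masked loss.

    One sigmoid output per assay; hidden layers use ReLU.  Optimised with
    Adam on :func:`masked_bce`; regularised by L2 weight decay, inverted
    dropout and early stopping on the masked loss of a held-out validation
    slice, which is carved from the training data by the same anticlustering
    routine used for the train/test split (label-profile encoding), keeping
    validation chemicals representative.  Assays with no observed validation
    label simply contribute no terms to the early-stopping metric.

    Desk-scale defaults (a single 64-unit hidden layer) are deliberate; widths
    in the hundreds-to-thousands range are configurable via
    ``hidden_layer_sizes``.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (64,),
        alpha: float = 1e-4,
        dropout: float = 0.0,
        batch_norm: bool = False,
        learning_rate: float = 1e-3,
        max_epochs: int = 200,
        batch_size: int = 256,
        early_stopping: bool = True,
        validation_fraction: float = 0.1,
        patience: int = 15,
        validation_split: str = "anticluster",
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.validation_split = validation_split
        self.random_state = random_state

    # -- parameter containers -----------------------------------------------

    def _init_params(self, d_in: int, d_out: int, rng) -> None:
        sizes = [d_in, *self.hidden_layer_sizes, d_out]
        self._W = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self._b = [np.zeros(b) for b in sizes[1:]]
        n_hidden = len(self.hidden_layer_sizes)
        if self.batch_norm:
            self._gamma = [np.ones(h) for h in self.hidden_layer_sizes]
            self._beta = [np.zeros(h) for h in self.hidden_layer_sizes]
            self._run_mean = [np.zeros(h) for h in self.hidden_layer_sizes]
            self._run_var = [np.ones(h) for h in self.hidden_layer_sizes]
        else:
            self._gamma = self._beta = []
        self._n_hidden = n_hidden

    def _params(self):
        return self._W + self._b + list(self._gamma) + list(self._beta)

    # -- forward / backward -------------------------------------------------

    def _forward(self, X, rng=None, train=False):
        """Returns logits and a cache for backprop."""
        cache = {"h": [X], "pre": [], "bn": [], "drop": []}
        h = X
        momentum = 0.9
        for layer in range(self._n_hidden):
            z = h @ self._W[layer] + self._b[layer]
            bn_cache = None
            if self.batch_norm:
                if train:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self._run_mean[layer] = (
                        momentum * self._run_mean[layer] + (1 - momentum) * mu
                    )
                    self._run_var[layer] = (
                        momentum * self._run_var[layer] + (1 - momentum) * var
                    )
                else:
                    mu, var = self._run_mean[layer], self._run_var[layer]
                zhat = (z - mu) / np.sqrt(var + 1e-5)
                bn_cache = (z, zhat, mu, var)
                z = self._gamma[layer] * zhat + self._beta[layer]
            cache["pre"].append(z)
            cache["bn"].append(bn_cache)
            h = np.maximum(z, 0.0)
            drop_mask = None
            if train and self.dropout > 0.0:
                drop_mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * drop_mask
            cache["drop"].append(drop_mask)
            cache["h"].append(h)
        logits = h @ self._W[-1] + self._b[-1]
        return logits, cache

    def _backward(self, dlogits, cache):
        gW = [None] * len(self._W)
        gb = [None] * len(self._b)
        ggamma = [None] * self._n_hidden if self.batch_norm else []
        gbeta = [None] * self._n_hidden if self.batch_norm else []

        gW[-1] = cache["h"][-1].T @ dlogits + self.alpha * self._W[-1]
        gb[-1] = dlogits.sum(axis=0)
        dh = dlogits @ self._W[-1].T
        for layer in range(self._n_hidden - 1, -1, -1):
            if cache["drop"][layer] is not None:
                dh = dh * cache["drop"][layer]
            dz = dh * (cache["pre"][layer] > 0)
            if self.batch_norm:
                z, zhat, mu, var = cache["bn"][layer]
                n = z.shape[0]
                ggamma[layer] = (dz * zhat).sum(axis=0)
                gbeta[layer] = dz.sum(axis=0)
                dzhat = dz * self._gamma[layer]
                inv_std = 1.0 / np.sqrt(var + 1e-5)
                dz = (
                    inv_std
                    / n
                    * (
                        n * dzhat
                        - dzhat.sum(axis=0)
                        - zhat * (dzhat * zhat).sum(axis=0)
                    )
                )
            gW[layer] = cache["h"][layer].T @ dz + self.alpha * self._W[layer]
            gb[layer] = dz.sum(axis=0)
            dh = dz @ self._W[layer].T
        return gW + gb + list(ggamma) + list(gbeta)

    @staticmethod
    def _masked_loss_from_logits(logits, y):
        mask = ~np.isnan(y)
        m = int(mask.sum())
        if m == 0:
            return 0.0, np.zeros_like(logits), 0
        z, t = logits[mask], y[mask]
        # stable BCE-with-logits: softplus(z) - t * z
        loss = float((np.logaddexp(0.0, z) - t * z).sum() / m)
        dlogits = np.zeros_like(logits)
        dlogits[mask] = (expit(z) - t) / m
        return loss, dlogits, m

    def _validation_indices(self, Y: pd.DataFrame, rng) -> np.ndarray:
        from .partitioning import anticluster, encode_labels

        n = len(Y)
        k = max(2, int(round(1.0 / self.validation_fraction)))
        if self.validation_split == "anticluster" and n >= 4 * k:
            assignment = anticluster(
                encode_labels(Y), k=k, max_sweeps=5, seed=int(rng.integers(2**31))
            )
            return assignment.groups == 0
        idx = rng.permutation(n)
        n_val = max(1, int(round(self.validation_fraction * n)))
        val = np.zeros(n, dtype=bool)
        val[idx[:n_val]] = True
        return val

    def fit(self, X, Y):
        rng = np.random.default_rng(self.random_state)
        if isinstance(X, pd.DataFrame):
            self.feature_ids_ = list(X.columns)
            X_arr = X.to_numpy(dtype=float)
        else:
            self.feature_ids_ = None
            X_arr = np.asarray(X, dtype=float)
        if isinstance(Y, pd.DataFrame):
            self.assay_ids_ = list(Y.columns)
            Y_frame = Y
        else:
            Y_frame = pd.DataFrame(np.asarray(Y, dtype=float))
            self.assay_ids_ = list(Y_frame.columns)
        Y_arr = Y_frame.to_numpy(dtype=float)
        observed_per_assay = (~np.isnan(Y_arr)).sum(axis=0)
        if (observed_per_assay == 0).any():
            bad = [self.assay_ids_[i] for i in np.flatnonzero(observed_per_assay == 0)]
            raise ValueError(f"assays with no observed labels: {bad}")

        if self.early_stopping:
            val_mask = self._validation_indices(Y_frame, rng)
        else:
            val_mask = np.zeros(len(Y_arr), dtype=bool)
        X_tr, Y_tr = X_arr[~val_mask], Y_arr[~val_mask]
        X_va, Y_va = X_arr[val_mask], Y_arr[val_mask]

        self._init_params(X_arr.shape[1], Y_arr.shape[1], rng)
        params = self._params()
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t_step = 0

        n_tr = len(X_tr)
        batch = self.batch_size or n_tr
        best_val, best_state, since_best = np.inf, None, 0
        self.training_log_ = []

        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n_tr, batch):
                rows = order[start : start + batch]
                logits, cache = self._forward(X_tr[rows], rng=rng, train=True)
                loss, dlogits, m = self._masked_loss_from_logits(logits, Y_tr[rows])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: non-finite loss"
                    )
                if m == 0:
                    continue
                grads = self._backward(dlogits, cache)
                t_step += 1
                params = self._params()
                for p, g, m_a, v_a in zip(params, grads, m_adam, v_adam):
                    m_a *= beta1
                    m_a += (1 - beta1) * g
                    v_a *= beta2
                    v_a += (1 - beta2) * g * g
                    mhat = m_a / (1 - beta1**t_step)
                    vhat = v_a / (1 - beta2**t_step)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                epoch_loss += loss
                n_batches += 1
            train_loss = epoch_loss / max(n_batches, 1)

            entry = {"epoch": epoch, "train_loss": train_loss}
            if self.early_stopping and len(X_va):
                logits_va, _ = self._forward(X_va, train=False)
                val_loss, _, m_va = self._masked_loss_from_logits(logits_va, Y_va)
                entry["val_loss"] = val_loss
                if m_va > 0 and val_loss < best_val - 1e-6:
                    best_val, since_best = val_loss, 0
                    best_state = [p.copy() for p in self._params()]
                else:
                    since_best += 1
                if since_best >= self.patience:
                    self.training_log_.append(entry)
                    break
            self.training_log_.append(entry)

        if best_state is not None:
            for p, bp in zip(self._params(), best_state):
                p[...] = bp
        self.n_assays_ = Y_arr.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def _align(self, X):
        if isinstance(X, pd.DataFrame) and self.feature_ids_ is not None:
            missing = [f for f in self.feature_ids_ if f not in X.columns]
            if missing:
                raise ValueError(f"missing required feature columns: {missing}")
            return X[self.feature_ids_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def predict_proba(self, X) -> np.ndarray:
        """Per-assay activity probabilities, shape (n_chemicals, n_assays)."""
        check_is_fitted(self, "n_assays_")
        logits, _ = self._forward(self._align(X), train=False)
        return expit(logits)

    # spec scoring contract
    def score_active(self, X) -> np.ndarray:
        return self.predict_proba(X)

    score = score_active

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def train_multi_output(X, labels, random_state: int | None = None, **params) -> MaskedMLPClassifier:
    """Fit the multi-output masked-loss network (see MaskedMLPClassifier)."""
    net = MaskedMLPClassifier(random_state=random_state, **params)
    return net.fit(X, labels)


def predict_scores(model, X: pd.DataFrame):
    """Uniform scoring entry point for both model families.

    Returns a Series (single-output) or a DataFrame with one column per assay
    (multi-output), indexed like ``X``.  Extra feature columns are ignored by
    name; a missing required column raises naming it.
    """
    scores = model.score_active(X)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(scores))
    if scores.ndim == 1:
        return pd.Series(scores, index=index, name="score")
    return pd.DataFrame(scores, index=index, columns=model.assay_ids_)
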
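"""Record deduplication, SMARTS fingerprinting and feature filtering.

Deduplication follows the "active in at least one experiment" rule used for
multi-assay screening collections: a chemical reported active in any replicate
of an assay is active; otherwise an observed inactive wins over inconclusive
runs; only chemicals with no conclusive replicate stay missing.

Feature filtering mirrors the caret-style preprocessing pair: near-zero
variance removal (frequency-ratio and percent-unique rule) followed by greedy
removal of highly correlated features until no surviving pair exceeds the
cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import FeatureFilterReport, validate_binary_table

__all__ = [
    "deduplicate",
    "compute_fingerprints",
    "NearZeroVarianceFilter",
    "CorrelationFilter",
    "filter_near_zero_variance",
    "filter_correlated",
]


def deduplicate(
    records: pd.DataFrame,
    missing_policy: str = "inactive-dominates",
) -> pd.DataFrame:
    """Collapse duplicated chemical records into one label row each.

    ``records`` has a ``chem_id`` column plus one column per assay with values
    in {1, 0, NaN}; a chemical may appear several times with conflicting
    results.  Per assay: any 1 among the duplicates gives 1; otherwise, under
    the default ``inactive-dominates`` policy, any observed 0 gives 0 and only
    all-missing stays missing.  The ``strict`` policy instead reports 0 only
    when every duplicate is an observed 0 (a single inconclusive run makes the
    consensus inconclusive).  Row order follows first appearance; the
    operation is idempotent.
    """
    if missing_policy not in ("inactive-dominates", "strict"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    if "chem_id" not in records.columns:
        raise ValueError("records must contain a 'chem_id' column")
    assay_cols = [c for c in records.columns if c != "chem_id"]
    values = records[assay_cols].to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if not np.isin(observed, (0.0, 1.0)).all():
        bad_rows = (~(np.isin(values, (0.0, 1.0)) | np.isnan(values))).any(axis=1)
        bad_ids = records.loc[bad_rows, "chem_id"].tolist()
        raise ValueError(f"labels outside {{0, 1, NaN}} in records for: {bad_ids}")

    grouped = records.groupby("chem_id", sort=False)[assay_cols]
    any_active = grouped.max()  # skipna: 1 if any duplicate active
    if missing_policy == "inactive-dominates":
        # any observed value at all -> max() is 0 or 1; all-missing -> NaN
        result = any_active
    else:
        n_obs = grouped.count()
        n_rec = grouped.size()
        all_inactive = any_active.eq(0) & n_obs.eq(n_rec, axis=0)
        result = any_active.where(any_active.eq(1) | all_inactive)
    result.index.name = None
    return result.astype(float)


def compute_fingerprints(
    smiles: dict[str, str] | list[str],
    smarts_patterns: dict[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """Substructure-match SMARTS patterns against SMILES structures.

    ``smiles`` maps chemical id to SMILES (a bare list gets positional ids);
    ``smarts_patterns`` maps feature id to a SMARTS query.  Bit (i, j) is 1
    iff chemical i contains at least one match of pattern j.  Unparseable
    SMARTS raise immediately (configuration error); unparseable SMILES are
    dropped from the table and returned as the second element, with a warning.
    """
    from rdkit import Chem

    if isinstance(smiles, list):
        smiles = {f"chem_{i:04d}": s for i, s in enumerate(smiles)}

    queries = {}
    bad_patterns = []
    for fid, smarts in smarts_patterns.items():
        q = Chem.MolFromSmarts(smarts)
        if q is None:
            bad_patterns.append(fid)
        else:
            queries[fid] = q
    if bad_patterns:
        raise ValueError(f"unparseable SMARTS patterns: {bad_patterns}")

    rows, kept, dropped = [], [], []
    for chem_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            dropped.append(chem_id)
            continue
        rows.append([int(mol.HasSubstructMatch(q)) for q in queries.values()])
        kept.append(chem_id)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} unparseable SMILES: {dropped}")

    table = pd.DataFrame(rows, index=kept, columns=list(queries), dtype=np.int8)
    return table, dropped


class NearZeroVarianceFilter(BaseEstimator, TransformerMixin):
    """Drop zero- and near-zero-variance features.

    A feature is removed when it has a single unique value, or when the ratio
    of its most frequent to second most frequent value count exceeds
    ``freq_cut`` (default 19, i.e. 95/5) *and* its percentage of distinct
    values is below ``unique_cut``.  For binary features this reduces to
    "minority prevalence below 1/(freq_cut+1)".

    Parameters
    ----------
    freq_cut : float, default 19.0
        Most-frequent / second-most-frequent count ratio above which a feature
        is a removal candidate.
    unique_cut : float, default 10.0
        Percent of distinct values (100 * n_unique / n_samples) below which a
        candidate is actually removed.
    """

    def __init__(self, freq_cut: float = 19.0, unique_cut: float = 10.0):
        self.freq_cut = freq_cut
        self.unique_cut = unique_cut

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        n = len(X)
        support = []
        for col in X.columns:
            counts = X[col].value_counts(dropna=False).to_numpy()
            if len(counts) < 2:
                support.append(False)
                continue
            freq_ratio = counts[0] / counts[1]
            pct_unique = 100.0 * len(counts) / n
            near_zero = freq_ratio > self.freq_cut and pct_unique < self.unique_cut
            support.append(not near_zero)
        self.support_ = np.asarray(support, dtype=bool)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.removed_ = list(self.feature_names_in_[~self.support_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        return X.loc[:, self.feature_names_in_[self.support_]]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return self.feature_names_in_[self.support_]


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Greedy removal of highly correlated feature pairs.

    While any surviving pair has ``|Pearson r| > cutoff``, the pair with the
    largest absolute correlation is located and the member with the larger
    mean absolute correlation to all other surviving features is removed (ties
    broken by removing the lower column index).  Mean correlations are
    recomputed after every removal (exhaustive variant), so the result is
    deterministic and order-independent.  Guarantees that no surviving pair
    exceeds the cutoff.  Constant columns correlate 0 by convention.
    """

    def __init__(self, cutoff: float = 0.9):
        self.cutoff = cutoff

    def fit(self, X: pd.DataFrame, y=None):
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 features")
        values = X.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(values, rowvar=False)
        corr = np.abs(np.nan_to_num(corr, nan=0.0))
        np.fill_diagonal(corr, 0.0)

        alive = np.ones(X.shape[1], dtype=bool)
        removed = []
        while True:
            sub = corr[np.ix_(alive, alive)]
            if sub.size == 0 or sub.max() <= self.cutoff:
                break
            alive_idx = np.flatnonzero(alive)
            i_s, j_s = np.unravel_index(np.argmax(sub), sub.shape)
            i, j = alive_idx[i_s], alive_idx[j_s]
            others = alive.copy()
            mean_i = corr[i, others].sum() / max(others.sum() - 1, 1)
            mean_j = corr[j, others].sum() / max(others.sum() - 1, 1)
            if mean_i > mean_j:
                drop = i
            elif mean_j > mean_i:
                drop = j
            else:
                drop = min(i, j)
            alive[drop] = False
            removed.append(X.columns[drop])

        self.support_ = alive
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.removed_ = removed
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        return X.loc[:, self.feature_names_in_[self.support_]]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return self.feature_names_in_[self.support_]


def filter_near_zero_variance(
    table: pd.DataFrame, freq_cut: float = 19.0, unique_cut: float = 10.0
) -> tuple[pd.DataFrame, FeatureFilterReport]:
    if table.shape[1] == 0:
        raise ValueError("fingerprint table has no features")
    f = NearZeroVarianceFilter(freq_cut=freq_cut, unique_cut=unique_cut).fit(table)
    out = f.transform(table)
    report = FeatureFilterReport(
        removed_near_zero=list(f.removed_),
        removed_correlated=[],
        surviving=list(out.columns),
    )
    return out, report


def filter_correlated(
    table: pd.DataFrame, cutoff: float
) -> tuple[pd.DataFrame, FeatureFilterReport]:
    f = CorrelationFilter(cutoff=cutoff).fit(table)
    out = f.transform(table)
    report = FeatureFilterReport(
        removed_near_zero=[],
        removed_correlated=list(f.removed_),
        surviving=list(out.columns),
        cutoff=cutoff,
    )
    return out, report
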
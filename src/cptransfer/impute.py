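"""Weighted K-nearest-neighbor imputation of missing feature columns.

For a target column with missing cells in one gene, the imputer picks the
few other columns most rank-correlated with the target in that gene,
standardizes them, scales each by its correlation weight (the target
itself gets weight 1), and fills each missing cell with the unweighted
mean of the target values of the nearest observed rows under nan-aware
Euclidean distance.  Two deployment modes exist:

* within-gene — for genes where the target is partially observed, a model
  fitted on that gene fills its own gaps;
* cross-gene — for genes where the target is entirely missing, models
  fitted on each training gene each predict the column and their outputs
  are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import FeatureTable


@dataclass
class ImputerSpec:
    """Knobs of the weighted-KNN imputer.

    ``n_neighbors`` observed rows are averaged per missing cell;
    ``n_helper_features`` auxiliary columns (most correlated with the
    target) span the distance space together with the target itself, which
    always carries ``target_weight``.  Neighbor averaging is uniform.
    """

    n_neighbors: int = 10
    n_helper_features: int = 5
    target_weight: float = 1.0
    signed_weights: bool = False

    def __post_init__(self):
        if self.n_neighbors < 1 or self.n_helper_features < 1:
            raise ValueError("n_neighbors and n_helper_features must be >= 1")


class TooFewObservedError(ValueError):
    """Within-gene fitting impossible; caller should fall back to cross-gene."""


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    """|rho|-ready Spearman over mutually observed entries; 0 when undefined."""
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 2:
        return 0.0
    x, y = a[mask], b[mask]
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return 0.0 if not np.isfinite(rho) else float(rho)


def nan_euclidean(q: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Distances from one query row to each reference row, NaN-aware.

    Squared differences are summed over mutually observed dimensions and
    rescaled by (total dims / observed dims); rows sharing no observed
    dimension get distance NaN.
    """
    d = q[None, :] - ref
    obs = np.isfinite(d)
    n_obs = obs.sum(axis=1)
    sq = np.where(obs, d, 0.0) ** 2
    total = ref.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(total / n_obs * sq.sum(axis=1))
    out[n_obs == 0] = np.nan
    return out


class WeightedKNNImputer(BaseEstimator):
    """Correlation-weighted KNN imputer for one target column of one gene.

    Parameters
    ----------
    target : str
        Name of the column to impute.
    n_neighbors, n_helper_features, target_weight, signed_weights
        See :class:`ImputerSpec`.  With ``signed_weights`` the raw Spearman
        rho is used as the scaling weight instead of |rho| (sign has no
        effect on Euclidean geometry, so results are identical; the option
        exists for auditability of the stored weights).

    Attributes (after ``fit``)
    --------------------------
    helper_names_ : selected helper column names, by descending |rho|.
    helper_weights_ : scaling weight per helper.
    feature_means_, feature_stds_ : standardization statistics per
        dimension of the weighted space (target first, then helpers).
    reference_ : weighted reference matrix (rows with observed target).
    reference_targets_ : target values of the reference rows.
    """

    def __init__(self, target: str, n_neighbors: int = 10,
                 n_helper_features: int = 5, target_weight: float = 1.0,
                 signed_weights: bool = False):
        self.target = target
        self.n_neighbors = n_neighbors
        self.n_helper_features = n_helper_features
        self.target_weight = target_weight
        self.signed_weights = signed_weights

    def _spec(self) -> ImputerSpec:
        return ImputerSpec(self.n_neighbors, self.n_helper_features,
                           self.target_weight, self.signed_weights)

    def fit(self, X: pd.DataFrame, y=None) -> "WeightedKNNImputer":
        """Fit on one gene's feature frame (columns include the target)."""
        spec = self._spec()
        if self.target not in X.columns:
            raise KeyError(f"target column {self.target!r} absent")
        tgt = X[self.target].to_numpy(dtype=float)
        observed = np.isfinite(tgt)
        if observed.sum() < spec.n_neighbors + 1:
            raise TooFewObservedError(
                f"{self.target}: {int(observed.sum())} observed values "
                f"< {spec.n_neighbors + 1}; use cross-gene imputation"
            )
        candidates = [c for c in X.columns if c != self.target]
        rhos: dict[str, float] = {}
        varying: list[str] = []
        for c in candidates:
            col = X[c].to_numpy(dtype=float)
            obs = col[np.isfinite(col)]
            if obs.size == 0 or np.all(obs == obs[0]):
                continue  # zero-variance helper: weight 0, excluded
            varying.append(c)
            rhos[c] = _spearman(col, tgt)
        ranked = sorted(varying, key=lambda c: (-abs(rhos[c]), varying.index(c)))
        self.helper_names_ = ranked[: spec.n_helper_features]
        self.helper_weights_ = np.array(
            [rhos[c] if spec.signed_weights else abs(rhos[c]) for c in self.helper_names_]
        )
        dims = [self.target] + self.helper_names_
        mat = X[dims].to_numpy(dtype=float)
        means, stds = [], []
        for j in range(mat.shape[1]):
            col = mat[:, j]
            m = np.nanmean(col) if np.isfinite(col).any() else 0.0
            s = np.nanstd(col) if np.isfinite(col).any() else 0.0
            means.append(m)
            stds.append(s if s > 0 else 1.0)
        self.feature_means_ = np.array(means)
        self.feature_stds_ = np.array(stds)
        self.dim_weights_ = np.concatenate(
            [[spec.target_weight], self.helper_weights_]
        )
        weighted = (mat - self.feature_means_) / self.feature_stds_ * self.dim_weights_
        self.reference_ = weighted[observed]
        self.reference_targets_ = tgt[observed]
        return self

    def _weighted_rows(self, X: pd.DataFrame) -> np.ndarray:
        dims = [self.target] + self.helper_names_
        missing_helpers = [c for c in dims if c not in X.columns]
        if missing_helpers:
            raise KeyError(f"helper columns absent: {missing_helpers}")
        mat = X[dims].to_numpy(dtype=float)
        return (mat - self.feature_means_) / self.feature_stds_ * self.dim_weights_

    def _impute_row(self, qrow: np.ndarray) -> float:
        d = nan_euclidean(qrow, self.reference_)
        valid = np.isfinite(d)
        if not valid.any():
            return np.nan
        idx = np.flatnonzero(valid)
        order = idx[np.argsort(d[idx], kind="stable")]  # ties -> lower row index
        k = min(self.n_neighbors, len(order))
        return float(self.reference_targets_[order[:k]].mean())

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Return the completed target column; observed cells untouched."""
        tgt = X[self.target].to_numpy(dtype=float).copy()
        weighted = self._weighted_rows(X)
        n_failed = 0
        for i in np.flatnonzero(~np.isfinite(tgt)):
            v = self._impute_row(weighted[i])
            if np.isnan(v):
                n_failed += 1
            else:
                tgt[i] = v
        if n_failed:
            warnings.warn(
                f"{self.target}: {n_failed} rows had no usable helper dimensions "
                "and remain missing"
            )
        return tgt

    def predict_column(self, X: pd.DataFrame) -> np.ndarray:
        """Predict the target for every row, ignoring any observed values."""
        X = X.copy()
        if self.target in X.columns:
            X[self.target] = np.nan
        else:
            X[self.target] = np.nan
        weighted = self._weighted_rows(X)
        return np.array([self._impute_row(w) for w in weighted])


class CrossGeneImputer(BaseEstimator):
    """Average of per-training-gene weighted-KNN predictions.

    For a gene where the target column is entirely missing, each imputer
    fitted on a training gene predicts the column from the helper
    features; predictions are averaged across the imputers that succeed.
    """

    def __init__(self, imputers: list[WeightedKNNImputer]):
        self.imputers = imputers

    def predict_column(self, X: pd.DataFrame) -> np.ndarray:
        preds = []
        for imp in self.imputers:
            try:
                preds.append(imp.predict_column(X))
            except KeyError as e:
                warnings.warn(f"cross-gene imputer skipped: {e}")
        if not preds:
            raise ValueError("all cross-gene imputers failed (helper columns absent)")
        return np.nanmean(np.vstack(preds), axis=0)


# ---------------------------------------------------------------------------
# Functional wrappers over the estimators
# ---------------------------------------------------------------------------


def fit_weighted_knn(table: FeatureTable, target: str,
                     spec: ImputerSpec | None = None) -> WeightedKNNImputer:
    """Fit a weighted-KNN imputer for ``target`` on one gene's FeatureTable."""
    spec = spec or ImputerSpec()
    genes = table.genes()
    if len(genes) != 1:
        raise ValueError(f"expected a single-gene table, got genes {genes}")
    imp = WeightedKNNImputer(target, spec.n_neighbors, spec.n_helper_features,
                             spec.target_weight, spec.signed_weights)
    return imp.fit(table.df)


def impute_within_gene(imputer: WeightedKNNImputer, table: FeatureTable,
                       target: str | None = None) -> np.ndarray:
    """Complete the imputer's target column for the gene it was fitted on."""
    if target is not None and target != imputer.target:
        raise ValueError(f"imputer was fitted for {imputer.target!r}, not {target!r}")
    return imputer.transform(table.df)


def impute_cross_gene(training_imputers: list[WeightedKNNImputer],
                      table: FeatureTable, target: str | None = None) -> np.ndarray:
    """Predict an entirely missing target column as the mean over imputers."""
    if target is not None:
        for imp in training_imputers:
            if imp.target != target:
                raise ValueError(
                    f"imputer targets {imp.target!r} but {target!r} requested"
                )
    return CrossGeneImputer(training_imputers).predict_column(table.df)


def impute_table(table: FeatureTable, spec: ImputerSpec | None = None,
                 cross_gene_refs: dict[str, "FeatureTable"] | None = None) -> FeatureTable:
    """Complete every feature column of a multi-gene table.

    Columns with enough observed values in a gene are imputed within that
    gene; columns entirely (or almost entirely) missing in a gene fall
    back to cross-gene imputation with models fitted on the reference
    genes (``cross_gene_refs``, defaulting to the other genes of the
    table).
    """
    spec = spec or ImputerSpec()
    out = table.subset(range(len(table)))
    for gene in table.genes():
        idx = [i for i, k in enumerate(out.keys) if k.gene == gene]
        sub = out.df.iloc[idx]
        for colname in out.feature_names:
            col = sub[colname].to_numpy(dtype=float)
            if np.isfinite(col).all():
                continue
            try:
                imp = WeightedKNNImputer(colname, spec.n_neighbors,
                                         spec.n_helper_features,
                                         spec.target_weight, spec.signed_weights)
                imp.fit(sub)
                completed = imp.transform(sub)
            except TooFewObservedError:
                refs = (cross_gene_refs or
                        {g: table.subset_gene(g) for g in table.genes() if g != gene})
                imps = []
                for ref in refs.values():
                    try:
                        fitted = WeightedKNNImputer(
                            colname, spec.n_neighbors, spec.n_helper_features,
                            spec.target_weight, spec.signed_weights).fit(ref.df)
                        imps.append(fitted)
                    except (TooFewObservedError, KeyError):
                        continue
                if not imps:
                    warnings.warn(f"{gene}/{colname}: no imputer available; left missing")
                    continue
                pred = CrossGeneImputer(imps).predict_column(sub)
                completed = np.where(np.isfinite(col), col, pred)
            out.df.iloc[idx, out.df.columns.get_loc(colname)] = completed
    return out
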
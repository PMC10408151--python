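"""Cross-protein transfer models: per-protein linear fits ensembled by averaging.

Assay score distributions differ strongly between proteins (batch
effects), so one linear or logistic model is fitted per training protein
and predictions are averaged at test time.  Features are rescaled to unit
standard deviation with every training protein reweighted to total weight
one (so large proteins do not dominate), except alignment-frequency
features which are left on their natural [0, ln 2] scale.  For
classification, assay scores are binarized per protein: top 40% of
variants functionally normal, bottom 40% abnormal, middle discarded.
Feature selection runs leave-one-protein-out cross-validation: an
exhaustive subset search per feature category, then greedy forward
selection of descriptor features; the two protein-homology score columns
are always included.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge

from .io import DMSDataset, FeatureTable, VariantKey
from .metrics import roc_auc, spearman_rho

#: Fixed category order for step-one exhaustive selection.
SELECTION_CATEGORIES = ("vert100", "mamm30", "inverse_folding", "conditioned")

MODEL_SCHEMA_VERSION = 1


@dataclass
class TrainingConfig:
    """Training knobs.

    ``top_fraction`` / ``bottom_fraction`` control the percentile
    binarization of assay scores for classification.  ``l2_strength`` is a
    tiny ridge penalty stabilizing collinear features (0 disables it).
    ``average`` chooses whether the classification ensemble averages
    predicted probabilities or log-odds.
    """

    top_fraction: float = 0.40
    bottom_fraction: float = 0.40
    task: str = "classification"
    l2_strength: float = 1e-6
    average: str = "probability"

    def __post_init__(self):
        for f in (self.top_fraction, self.bottom_fraction):
            if not 0 < f <= 0.5:
                raise ValueError("fractions must lie in (0, 0.5]")
        if self.top_fraction + self.bottom_fraction > 1:
            raise ValueError("top + bottom fractions must be <= 1")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.average not in ("probability", "log_odds"):
            raise ValueError(f"unknown averaging {self.average!r}")


def binarize_dms(dms: DMSDataset, config: TrainingConfig | None = None
                 ) -> tuple[list[VariantKey], np.ndarray]:
    """Percentile-binarize assay scores: high fitness 0 (normal), low 1 (abnormal).

    The bottom ``floor(bottom_fraction * n)`` variants by score are labeled
    functionally abnormal (1) and the top ``floor(top_fraction * n)``
    functionally normal (0); the middle band is discarded.  Ties are broken
    by stable input order, so label counts are exact for any score
    distribution.
    """
    config = config or TrainingConfig()
    dms.require_trainable()
    n = len(dms)
    order = np.argsort(dms.scores, kind="stable")  # ascending; stable under ties
    n_bottom = int(np.floor(config.bottom_fraction * n))
    n_top = int(np.floor(config.top_fraction * n))
    bottom = order[:n_bottom]
    top = order[n - n_top:]
    keys = [dms.keys[i] for i in bottom] + [dms.keys[i] for i in top]
    labels = np.concatenate([np.ones(n_bottom, dtype=int), np.zeros(n_top, dtype=int)])
    return keys, labels


def fit_rescaler(tables: dict[str, FeatureTable],
                 features: list[str] | None = None) -> dict[str, float]:
    """Per-feature scale factors (1/std) with proteins reweighted to weight one.

    Each row of protein p carries weight 1/n_p, so every training protein
    contributes equally to the standard deviation regardless of size.
    Frequency-flagged features keep scale 1 (their [0, ln 2] range is
    already comparable and does not behave well under std rescaling).
    Features are not mean-centered; the per-protein intercepts absorb
    location.
    """
    if not tables:
        raise ValueError("at least one training protein required")
    any_table = next(iter(tables.values()))
    if features is None:
        features = any_table.feature_names
    freq_cols = {
        c for t in tables.values() for c in t.frequency_columns()
    }
    scales: dict[str, float] = {}
    for feat in features:
        if feat in freq_cols:
            scales[feat] = 1.0
            continue
        vals, wts = [], []
        for t in tables.values():
            col = t.df[feat].to_numpy(dtype=float)
            obs = col[np.isfinite(col)]
            if obs.size:
                vals.append(obs)
                wts.append(np.full(obs.size, 1.0 / obs.size))
        if not vals:
            raise ValueError(f"feature {feat!r} has no observed values")
        v = np.concatenate(vals)
        w = np.concatenate(wts)
        if v.size < 2:
            raise ValueError(f"feature {feat!r} observed in < 2 rows")
        mean = np.average(v, weights=w)
        var = np.average((v - mean) ** 2, weights=w)
        std = np.sqrt(var)
        if std <= 0:
            warnings.warn(f"feature {feat!r} has zero weighted std; scale set to 1")
            scales[feat] = 1.0
        else:
            scales[feat] = 1.0 / std
    return scales


def _align_dms_to_table(table: FeatureTable, keys: list[VariantKey]) -> np.ndarray:
    index = {k: i for i, k in enumerate(table.keys)}
    try:
        return np.array([index[k] for k in keys])
    except KeyError as e:
        raise ValueError(f"variant {e.args[0]} absent from feature table") from e


class _CPTBase(BaseEstimator):
    """Shared machinery of the regression and classification transfer models."""

    def __init__(self, features: list[str] | None = None,
                 l2_strength: float = 1e-6, average: str = "probability"):
        self.features = features
        self.l2_strength = l2_strength
        self.average = average

    # -- fitting -----------------------------------------------------------

    def fit_tables(self, tables: dict[str, FeatureTable],
                   dms: dict[str, DMSDataset]) -> "_CPTBase":
        """Fit per-protein sub-models from FeatureTables and DMS datasets."""
        if len(tables) < 2:
            raise ValueError("need >= 2 training proteins for a transferable model")
        features = self.features or next(iter(tables.values())).feature_names
        self.selected_features_ = list(features)
        self.scale_ = fit_rescaler(tables, self.selected_features_)
        self.models_ = {}
        for gene, table in tables.items():
            X, y = self._training_xy(table, dms[gene])
            if X is None:
                continue
            fitted = self._fit_one(X, y)
            if fitted is not None:
                self.models_[gene] = fitted
        if not self.models_:
            raise ValueError("no protein yielded a usable sub-model")
        return self

    def _design(self, table: FeatureTable) -> np.ndarray:
        for feat in self.selected_features_:
            if feat not in table.df.columns:
                raise ValueError(f"selected feature {feat!r} absent from table")
        X = table.df[self.selected_features_].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError(
                "feature table contains missing cells; run imputation first"
            )
        scale = np.array([self.scale_[f] for f in self.selected_features_])
        return X * scale

    # -- prediction --------------------------------------------------------

    def predict_table(self, table: FeatureTable) -> np.ndarray:
        """Ensemble prediction: mean of per-protein sub-model outputs."""
        X = self._design(table)
        preds = np.vstack([self._predict_one(m, X) for m in self.models_.values()])
        out = preds.mean(axis=0)
        return self._finalize(out)

    def _finalize(self, avg: np.ndarray) -> np.ndarray:
        return avg

    # -- sklearn array interface ------------------------------------------

    def fit(self, X, y, groups=None):
        """Array-based fit: X features, y assay scores, groups protein labels.

        Thin adapter over :meth:`fit_tables` so the model composes with
        sklearn tooling; rows are wrapped into per-protein tables keyed by
        synthetic variant identifiers.
        """
        from .io import ColumnMeta

        X = pd.DataFrame(X).reset_index(drop=True)
        X.columns = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=float)
        if groups is None:
            raise ValueError("groups (per-row protein labels) are required")
        groups = np.asarray([str(g) for g in groups])
        features = [str(f) for f in (self.features or X.columns)]
        meta = {c: ColumnMeta("homology") for c in features}
        tables, dms = {}, {}
        for g in dict.fromkeys(groups):
            sel = groups == g
            sub = X.loc[sel, features].reset_index(drop=True)
            keys = [VariantKey(g, i + 1, "A", "V") for i in range(len(sub))]
            tables[g] = FeatureTable(
                keys, {c: sub[c].to_numpy(dtype=float) for c in features}, meta)
            dms[g] = DMSDataset(gene=g, keys=keys, scores=y[sel])
        return self.fit_tables(tables, dms)

    def predict(self, X):
        """Array-based ensemble prediction over a feature matrix."""
        from .io import ColumnMeta

        X = pd.DataFrame(X).reset_index(drop=True)
        X.columns = [str(c) for c in X.columns]
        meta = {c: ColumnMeta("homology") for c in self.selected_features_}
        keys = [VariantKey("query", i + 1, "A", "V") for i in range(len(X))]
        table = FeatureTable(
            keys,
            {c: X[c].to_numpy(dtype=float) for c in self.selected_features_},
            meta,
        )
        return self.predict_table(table)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "task": self._task,
            "l2_strength": self.l2_strength,
            "average": self.average,
            "selected_features": self.selected_features_,
            "scale": self.scale_,
            "per_protein_models": {
                g: {"coef": list(map(float, c)), "intercept": float(b)}
                for g, (c, b) in self.models_.items()
            },
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def _restore(cls, obj: "_CPTBase", d: dict) -> "_CPTBase":
        obj.selected_features_ = list(d["selected_features"])
        obj.scale_ = dict(d["scale"])
        obj.models_ = {
            g: (np.array(m["coef"], dtype=float), float(m["intercept"]))
            for g, m in d["per_protein_models"].items()
        }
        return obj


class CPTRegressor(RegressorMixin, _CPTBase):
    """Transfer model predicting continuous assay scores.

    One least-squares (optionally tiny-ridge) fit per training protein on
    its raw assay scores; test-time predictions are the mean of the
    per-protein linear predictions.
    """

    _task = "regression"

    def __init__(self, features: list[str] | None = None, l2_strength: float = 1e-6):
        super().__init__(features=features, l2_strength=l2_strength)

    def _training_xy(self, table: FeatureTable, dms: DMSDataset):
        idx = _align_dms_to_table(table, dms.keys)
        X = self._design(table.subset(idx))
        return X, np.asarray(dms.scores, dtype=float)

    def _fit_one(self, X, y):
        if self.l2_strength > 0:
            model = Ridge(alpha=self.l2_strength)
        else:
            model = LinearRegression()
        model.fit(X, y)
        return (np.asarray(model.coef_, dtype=float).ravel(), float(model.intercept_))

    def _predict_one(self, model, X):
        coef, intercept = model
        return X @ coef + intercept

    @classmethod
    def from_dict(cls, d: dict) -> "CPTRegressor":
        obj = cls(features=d["selected_features"], l2_strength=d["l2_strength"])
        return cls._restore(obj, d)


class CPTClassifier(ClassifierMixin, _CPTBase):
    """Transfer model classifying functionally abnormal (1) vs normal (0).

    Assay scores are percentile-binarized per protein before fitting a
    logistic regression per protein; the ensemble averages predicted
    probabilities of the abnormal class (or log-odds, per config).
    """

    _task = "classification"

    def __init__(self, features: list[str] | None = None, l2_strength: float = 1e-6,
                 average: str = "probability", top_fraction: float = 0.40,
                 bottom_fraction: float = 0.40):
        super().__init__(features=features, l2_strength=l2_strength, average=average)
        self.top_fraction = top_fraction
        self.bottom_fraction = bottom_fraction

    def _training_xy(self, table: FeatureTable, dms: DMSDataset):
        config = TrainingConfig(top_fraction=self.top_fraction,
                                bottom_fraction=self.bottom_fraction)
        keys, labels = binarize_dms(dms, config)
        if len(set(labels.tolist())) < 2:
            warnings.warn(f"{dms.gene}: single class after binarization; excluded")
            return None, None
        idx = _align_dms_to_table(table, keys)
        X = self._design(table.subset(idx))
        return X, labels

    def _fit_one(self, X, y):
        C = 1e12 if self.l2_strength <= 0 else 1.0 / self.l2_strength
        model = LogisticRegression(C=C, max_iter=5000)
        model.fit(X, y)
        return (np.asarray(model.coef_, dtype=float).ravel(), float(model.intercept_[0]))

    def _predict_one(self, model, X):
        coef, intercept = model
        logits = X @ coef + intercept
        if self.average == "log_odds":
            return logits
        return expit(logits)

    def _finalize(self, avg: np.ndarray) -> np.ndarray:
        if self.average == "log_odds":
            return expit(avg)
        return avg

    @classmethod
    def from_dict(cls, d: dict) -> "CPTClassifier":
        obj = cls(features=d["selected_features"], l2_strength=d["l2_strength"],
                  average=d.get("average", "probability"))
        return cls._restore(obj, d)


def load_model_json(path: str | Path):
    d = json.loads(Path(path).read_text())
    if d.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {d.get('schema_version')}")
    cls = CPTRegressor if d["task"] == "regression" else CPTClassifier
    return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def fit_cpt(tables: dict[str, FeatureTable], dms: dict[str, DMSDataset],
            features: list[str] | None = None,
            config: TrainingConfig | None = None):
    """Fit a transfer model (classifier or regressor per config) on all proteins."""
    config = config or TrainingConfig()
    if config.task == "regression":
        model = CPTRegressor(features=features, l2_strength=config.l2_strength)
    else:
        model = CPTClassifier(features=features, l2_strength=config.l2_strength,
                              average=config.average,
                              top_fraction=config.top_fraction,
                              bottom_fraction=config.bottom_fraction)
    return model.fit_tables(tables, dms)


def predict_ensemble(model, table: FeatureTable) -> np.ndarray:
    """Per-variant ensemble prediction (mean over per-protein sub-models)."""
    return model.predict_table(table)


def lopo_folds(proteins: list[str]) -> list[tuple[list[str], str]]:
    """Leave-one-protein-out folds: each protein validates exactly once."""
    if len(proteins) < 2:
        raise ValueError("need >= 2 proteins for leave-one-protein-out folds")
    return [([p for p in proteins if p != held], held) for held in proteins]


def _lopo_metric(feature_set: list[str], tables: dict[str, FeatureTable],
                 dms: dict[str, DMSDataset], config: TrainingConfig) -> float:
    """Mean validation metric over leave-one-protein-out folds."""
    scores = []
    for train, held in lopo_folds(list(tables)):
        model = fit_cpt({g: tables[g] for g in train},
                        {g: dms[g] for g in train},
                        features=feature_set, config=config)
        held_table = tables[held]
        pred = model.predict_table(held_table)
        idx = _align_dms_to_table(held_table, dms[held].keys)
        if config.task == "regression":
            m = spearman_rho(np.asarray(dms[held].scores), pred[idx])
        else:
            keys, labels = binarize_dms(dms[held], config)
            vidx = _align_dms_to_table(held_table, keys)
            m = roc_auc(labels, pred[vidx])
        if np.isfinite(m):
            scores.append(m)
    return float(np.mean(scores)) if scores else -np.inf


def select_features(candidates: dict[str, list[str]],
                    tables: dict[str, FeatureTable],
                    dms: dict[str, DMSDataset],
                    config: TrainingConfig | None = None) -> list[str]:
    """Two-step feature selection by leave-one-protein-out validation.

    Always starts from the two protein-homology score columns
    (``candidates['homology']``).  Step one walks the fixed category order
    (100-vertebrate, 30-mammal, inverse-folding, conditioned scores) and
    appends, per non-empty category, the non-empty subset maximizing the
    mean validation metric (AUROC for classification, Spearman for
    regression).  Step two greedily appends descriptor features while the
    metric strictly improves.  Deterministic given the data: subsets are
    enumerated in a fixed order and ties keep the earliest winner.
    """
    config = config or TrainingConfig()
    homology = candidates.get("homology", [])
    if len(homology) != 2:
        raise ValueError("exactly two always-included homology features required")
    selected = list(homology)
    for category in SELECTION_CATEGORIES:
        names = candidates.get(category, [])
        if not names:
            continue
        best_subset, best_metric = None, -np.inf
        for size in range(1, len(names) + 1):
            for subset in itertools.combinations(names, size):
                metric = _lopo_metric(selected + list(subset), tables, dms, config)
                if metric > best_metric:
                    best_subset, best_metric = list(subset), metric
        selected += best_subset
    descriptors = candidates.get("descriptor", [])
    current = _lopo_metric(selected, tables, dms, config)
    remaining = list(descriptors)
    while remaining:
        best_feat, best_metric = None, current
        for feat in remaining:
            metric = _lopo_metric(selected + [feat], tables, dms, config)
            if metric > best_metric:
                best_feat, best_metric = feat, metric
        if best_feat is None:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        current = best_metric
    return selected
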
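"""Binarization, rescaling, per-protein fitting, ensembling, feature selection."""

import numpy as np
import pandas as pd
import pytest

from cptransfer import (ColumnMeta, CPTClassifier, CPTRegressor, DMSDataset,
                        FeatureTable, TrainingConfig, VariantKey, binarize_dms,
                        fit_cpt, fit_rescaler, lopo_folds, predict_ensemble,
                        select_features)
from cptransfer.model import load_model_json


def dms_from_scores(scores, gene="G"):
    keys = [VariantKey(gene, i + 1, "A", "V") for i in range(len(scores))]
    return DMSDataset(gene=gene, keys=keys, scores=np.asarray(scores, dtype=float))


def table_from_cols(cols, gene="G", freq=(), categories=None):
    n = len(next(iter(cols.values())))
    keys = [VariantKey(gene, i + 1, "A", "V") for i in range(n)]
    meta = {
        c: ColumnMeta((categories or {}).get(c, "homology"), is_frequency=c in freq)
        for c in cols
    }
    return FeatureTable(keys, {c: np.asarray(v, dtype=float) for c, v in cols.items()}, meta)


class TestBinarize:
    def test_scores_one_to_ten(self):
        keys, labels = binarize_dms(dms_from_scores(range(1, 11)))
        by_pos = {k.position: l for k, l in zip(keys, labels)}
        assert {p for p, l in by_pos.items() if l == 1} == {1, 2, 3, 4}
        assert {p for p, l in by_pos.items() if l == 0} == {7, 8, 9, 10}
        assert 5 not in by_pos and 6 not in by_pos

    def test_floor_rule_small_n(self):
        keys, labels = binarize_dms(dms_from_scores(range(11)))
        assert (labels == 1).sum() == 4 and (labels == 0).sum() == 4

    def test_all_ties_stable_order_split(self):
        keys, labels = binarize_dms(dms_from_scores([5.0] * 10))
        assert (labels == 1).sum() == 4 and (labels == 0).sum() == 4
        # stable sort: earliest input rows become the "bottom"
        abnormal = {k.position for k, l in zip(keys, labels) if l == 1}
        assert abnormal == {1, 2, 3, 4}

    @pytest.mark.parametrize("n", [10, 11, 25, 137, 500])
    def test_exact_floor_counts(self, n, rng):
        keys, labels = binarize_dms(dms_from_scores(rng.standard_normal(n)))
        assert (labels == 1).sum() == int(np.floor(0.4 * n))
        assert (labels == 0).sum() == int(np.floor(0.4 * n))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="10"):
            binarize_dms(dms_from_scores(range(9)))


class TestRescaler:
    def test_single_protein_inverse_std(self, rng):
        x = rng.standard_normal(50) * 2.0
        t = table_from_cols({"f": x})
        scale = fit_rescaler({"G": t})
        assert scale["f"] == pytest.approx(1.0 / x.std())

    def test_duplication_invariance(self, rng):
        xa, xb = rng.standard_normal(30), rng.standard_normal(40) + 3
        ta = table_from_cols({"f": xa}, gene="A")
        tb = table_from_cols({"f": xb}, gene="B")
        base = fit_rescaler({"A": ta, "B": tb})
        tb2 = table_from_cols({"f": np.concatenate([xb, xb])}, gene="B")
        dup = fit_rescaler({"A": ta, "B": tb2})
        assert dup["f"] == pytest.approx(base["f"])

    def test_frequency_columns_left_as_is(self, rng):
        t = table_from_cols({"freq": rng.uniform(0, 0.7, 30)}, freq={"freq"})
        assert fit_rescaler({"G": t})["freq"] == 1.0

    def test_zero_std_warns_and_returns_one(self):
        t = table_from_cols({"f": np.ones(5)})
        with pytest.warns(UserWarning, match="zero weighted std"):
            assert fit_rescaler({"G": t})["f"] == 1.0


class TestFitPredict:
    def make_pair(self, rng, gene, coef=(2.0, -1.0), offset=0.0, n=40):
        X = rng.standard_normal((n, 2))
        y = X @ np.array(coef) + offset
        t = table_from_cols({"x1": X[:, 0], "x2": X[:, 1]}, gene=gene)
        keys = t.keys
        return t, DMSDataset(gene=gene, keys=keys, scores=y)

    def test_regression_recovers_coefficients(self, rng):
        tables, dms = {}, {}
        for g in ("A", "B"):
            tables[g], dms[g] = self.make_pair(rng, g)
        model = fit_cpt(tables, dms, config=TrainingConfig(task="regression",
                                                           l2_strength=0.0))
        for coef, intercept in model.models_.values():
            unscaled = coef * np.array([model.scale_["x1"], model.scale_["x2"]])
            assert np.allclose(unscaled, [2.0, -1.0], atol=1e-8)

    def test_identical_proteins_identical_submodels(self, rng):
        t, d = self.make_pair(rng, "A")
        t2 = table_from_cols({"x1": t.df["x1"], "x2": t.df["x2"]}, gene="B")
        d2 = DMSDataset(gene="B", keys=t2.keys, scores=d.scores)
        model = fit_cpt({"A": t, "B": t2}, {"A": d, "B": d2},
                        config=TrainingConfig(task="regression"))
        (ca, ba), (cb, bb) = model.models_.values()
        assert np.allclose(ca, cb) and ba == pytest.approx(bb)

    def test_classifier_separable_sign(self, rng):
        tables, dms = {}, {}
        for g in ("A", "B"):
            x = np.linspace(-2, 2, 40)
            t = table_from_cols({"x1": x, "x2": rng.standard_normal(40)}, gene=g)
            dms[g] = DMSDataset(gene=g, keys=t.keys, scores=x)  # fitness = x1
            tables[g] = t
        model = fit_cpt(tables, dms, config=TrainingConfig(task="classification"))
        for coef, _ in model.models_.values():
            assert coef[0] < 0  # high x1 = high fitness = class 0

    def test_ensemble_mean_and_permutation_invariance(self, rng):
        t, d = self.make_pair(rng, "A")
        t2 = table_from_cols({"x1": t.df["x1"], "x2": t.df["x2"]}, gene="B")
        d2 = DMSDataset(gene="B", keys=t2.keys, scores=d.scores)
        model = fit_cpt({"A": t, "B": t2}, {"A": d, "B": d2},
                        config=TrainingConfig(task="regression"))
        # identical sub-models -> ensemble equals a single sub-model
        coef, intercept = next(iter(model.models_.values()))
        X = model._design(t)
        assert np.allclose(predict_ensemble(model, t), X @ coef + intercept)
        # hand-check averaging of two fixed sub-models
        model.models_ = {"A": (np.zeros(2), -1.0), "B": (np.zeros(2), 3.0)}
        assert np.allclose(predict_ensemble(model, t), 1.0)
        model.models_ = {"B": (np.zeros(2), 3.0), "A": (np.zeros(2), -1.0)}
        assert np.allclose(predict_ensemble(model, t), 1.0)

    def test_missing_cells_rejected_with_pointer_to_imputation(self, rng):
        t, d = self.make_pair(rng, "A")
        t2, d2 = self.make_pair(rng, "B")
        model = fit_cpt({"A": t, "B": t2}, {"A": d, "B": d2},
                        config=TrainingConfig(task="regression"))
        bad = table_from_cols({"x1": [np.nan], "x2": [0.0]})
        with pytest.raises(ValueError, match="imputation"):
            predict_ensemble(model, bad)

    def test_json_roundtrip(self, rng, tmp_path):
        t, d = self.make_pair(rng, "A")
        t2, d2 = self.make_pair(rng, "B")
        model = fit_cpt({"A": t, "B": t2}, {"A": d, "B": d2},
                        config=TrainingConfig(task="regression"))
        model.save_json(tmp_path / "m.json")
        back = load_model_json(tmp_path / "m.json")
        assert np.allclose(back.predict_table(t), model.predict_table(t))

    def test_sklearn_array_interface(self, rng):
        X = rng.standard_normal((60, 2))
        y = X @ np.array([1.0, 2.0])
        groups = np.repeat(["A", "B", "C"], 20)
        est = CPTRegressor(l2_strength=0.0).fit(pd.DataFrame(X, columns=["a", "b"]),
                                                y, groups=groups)
        pred = est.predict(pd.DataFrame(X, columns=["a", "b"]))
        assert np.allclose(pred, y, atol=1e-8)
        params = est.get_params()
        assert "l2_strength" in params


class TestLopoFolds:
    def test_counts(self):
        assert len(lopo_folds(list("ABCDE"))) == 5
        assert len(lopo_folds(list("AB"))) == 2

    def test_partition_property(self):
        folds = lopo_folds(list("ABCD"))
        held = [h for _, h in folds]
        assert sorted(held) == list("ABCD")
        for train, h in folds:
            assert h not in train and len(train) == 3

    def test_too_few(self):
        with pytest.raises(ValueError):
            lopo_folds(["A"])


class TestSelectFeatures:
    def build_family(self, rng, n_proteins=4, n=60):
        """Planted-signal family: one informative feature per category."""
        categories = {
            "esm": "homology", "eve": "homology",
            "v_sig": "vert100", "v_n1": "vert100", "v_n2": "vert100",
            "m_sig": "mamm30", "m_n1": "mamm30",
            "p_sig": "inverse_folding", "p_n1": "inverse_folding",
            "c_sig": "conditioned", "c_n1": "conditioned",
            "d_sig": "descriptor", "d_n1": "descriptor", "d_n2": "descriptor",
        }
        weights = {"esm": 1.0, "eve": 1.0, "v_sig": 1.5, "m_sig": 1.0,
                   "p_sig": 0.8, "c_sig": 0.7, "d_sig": 0.6}
        tables, dms = {}, {}
        for i in range(n_proteins):
            g = f"P{i}"
            cols = {c: rng.standard_normal(n) for c in categories}
            t = table_from_cols(cols, gene=g, categories=categories)
            y = sum(w * cols[c] for c, w in weights.items()) + (i - 1) * 0.5
            dms[g] = DMSDataset(gene=g, keys=t.keys, scores=y)
            tables[g] = t
        cands = {}
        for c, cat in categories.items():
            cands.setdefault(cat, []).append(c)
        return cands, tables, dms

    def test_planted_features_selected_and_homology_first(self, rng):
        cands, tables, dms = self.build_family(rng)
        selected = select_features(cands, tables, dms,
                                   TrainingConfig(task="regression"))
        assert selected[:2] == ["esm", "eve"]
        for planted in ("v_sig", "m_sig", "p_sig", "c_sig", "d_sig"):
            assert planted in selected

    def test_deterministic_across_runs(self, rng):
        cands, tables, dms = self.build_family(rng)
        cfg = TrainingConfig(task="regression")
        a = select_features(cands, tables, dms, cfg)
        b = select_features(cands, tables, dms, cfg)
        assert a == b

    def test_requires_two_homology_columns(self, rng):
        cands, tables, dms = self.build_family(rng)
        cands["homology"] = ["esm"]
        with pytest.raises(ValueError, match="two"):
            select_features(cands, tables, dms, TrainingConfig(task="regression"))
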
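"""Weighted-KNN imputation: helper selection, distances, cross-gene averaging."""

import numpy as np
import pandas as pd
import pytest

from cptransfer import (ColumnMeta, FeatureTable, ImputerSpec, VariantKey,
                        WeightedKNNImputer, fit_weighted_knn,
                        impute_cross_gene, impute_within_gene)
from cptransfer.impute import CrossGeneImputer, TooFewObservedError
from oracles import knn_impute_oracle


def table_from_array(arr, gene="G"):
    arr = np.asarray(arr, dtype=float)
    keys = [VariantKey(gene, i + 1, "A", "V") for i in range(len(arr))]
    cols = {f"f{j}": arr[:, j] for j in range(arr.shape[1])}
    meta = {c: ColumnMeta("homology") for c in cols}
    return FeatureTable(keys, cols, meta)


def random_missing_table(rng, n_rows, n_cols, missing_frac):
    arr = rng.standard_normal((n_rows, n_cols))
    # correlate columns with column 0 so helpers exist
    for j in range(1, n_cols):
        arr[:, j] = rng.uniform(-1, 1) * arr[:, 0] + 0.5 * arr[:, j]
    mask = rng.random((n_rows, n_cols)) < missing_frac
    arr[mask] = np.nan
    return arr


class TestFit:
    def test_perfectly_correlated_helper_gets_weight_one(self, rng):
        x = rng.standard_normal(20)
        df = pd.DataFrame({"t": x, "h": 2 * x + 1, "n": rng.standard_normal(20)})
        imp = WeightedKNNImputer("t", n_neighbors=3).fit(df)
        assert imp.helper_names_[0] == "h"
        assert imp.helper_weights_[0] == pytest.approx(1.0)

    def test_constant_helper_excluded(self, rng):
        df = pd.DataFrame({"t": rng.standard_normal(20), "c": np.ones(20)})
        imp = WeightedKNNImputer("t", n_neighbors=3).fit(df)
        assert "c" not in imp.helper_names_

    def test_engineered_rho_ranking(self):
        x = np.arange(15.0)
        df = pd.DataFrame({
            "t": x,
            "up": x ** 2,            # rho = +1
            "down": -x,              # rho = -1
            "flat": np.ones(15),     # rho undefined -> 0
        })
        imp = WeightedKNNImputer("t", n_neighbors=3, n_helper_features=2).fit(df)
        assert set(imp.helper_names_) == {"up", "down"}
        assert np.allclose(np.abs(imp.helper_weights_), 1.0)

    def test_too_few_observed_signals_cross_gene(self):
        df = pd.DataFrame({"t": [1.0] * 5 + [np.nan] * 10,
                           "h": np.arange(15.0)})
        with pytest.raises(TooFewObservedError):
            WeightedKNNImputer("t", n_neighbors=10).fit(df)


class TestWithinGene:
    def test_constant_neighborhood(self, rng):
        arr = rng.standard_normal((15, 3))
        arr[:, 0] = 7.25
        arr[4, 0] = np.nan
        table = table_from_array(arr)
        imp = fit_weighted_knn(table, "f0", ImputerSpec(n_neighbors=5))
        out = impute_within_gene(imp, table)
        assert out[4] == pytest.approx(7.25)

    def test_no_missing_is_identity(self, rng):
        arr = rng.standard_normal((15, 3))
        table = table_from_array(arr)
        imp = fit_weighted_knn(table, "f0", ImputerSpec(n_neighbors=5))
        assert np.allclose(impute_within_gene(imp, table), arr[:, 0])

    def test_twelve_row_toy_matches_exhaustive_oracle(self, rng):
        arr = rng.standard_normal((12, 4))
        arr[:, 1] = 0.9 * arr[:, 0] + 0.1 * arr[:, 1]
        arr[3, 0] = np.nan
        table = table_from_array(arr)
        imp = fit_weighted_knn(table, "f0", ImputerSpec(n_neighbors=10))
        out = impute_within_gene(imp, table)
        exp = knn_impute_oracle(arr, 0, n_neighbors=10, n_helpers=5)
        assert out[3] == pytest.approx(exp[3])

    def test_random_tables_match_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(12, 50))
            d = int(rng.integers(2, 8))
            arr = random_missing_table(rng, n, d, missing_frac=0.2)
            tgt_col = arr[:, 0]
            if np.isfinite(tgt_col).sum() < 11 or np.isfinite(tgt_col).all():
                continue
            df = pd.DataFrame({f"f{j}": arr[:, j] for j in range(d)})
            imp = WeightedKNNImputer("f0").fit(df)
            got = imp.transform(df)
            exp = knn_impute_oracle(arr, 0, n_neighbors=10, n_helpers=5)
            both = np.isfinite(got) & np.isfinite(exp)
            assert np.allclose(got[both], exp[both])
            assert (np.isnan(got) == np.isnan(exp)).all()

    def test_imputed_values_within_reference_range(self, rng):
        arr = random_missing_table(rng, 40, 5, missing_frac=0.25)
        df = pd.DataFrame({f"f{j}": arr[:, j] for j in range(5)})
        tgt = arr[:, 0]
        if np.isfinite(tgt).sum() < 11:
            pytest.skip("unlucky draw")
        imp = WeightedKNNImputer("f0").fit(df)
        out = imp.transform(df)
        obs = tgt[np.isfinite(tgt)]
        filled = out[~np.isfinite(tgt) & np.isfinite(out)]
        assert (filled >= obs.min() - 1e-12).all()
        assert (filled <= obs.max() + 1e-12).all()

    def test_row_permutation_invariance(self, rng):
        arr = random_missing_table(rng, 30, 4, missing_frac=0.15)
        arr[:, 0] = np.where(np.isfinite(arr[:, 0]), arr[:, 0], np.nan)
        df = pd.DataFrame({f"f{j}": arr[:, j] for j in range(4)})
        if np.isfinite(arr[:, 0]).sum() < 11:
            pytest.skip("unlucky draw")
        out1 = WeightedKNNImputer("f0").fit(df).transform(df)
        perm = rng.permutation(len(df))
        dfp = df.iloc[perm].reset_index(drop=True)
        out2 = WeightedKNNImputer("f0").fit(dfp).transform(dfp)
        # same cells get the same values regardless of row order
        back = np.empty_like(out2)
        back[perm] = out2
        both = np.isfinite(out1) & np.isfinite(back)
        assert np.allclose(out1[both], back[both])


class TestAgainstStockImputer:
    def test_weighted_space_agrees_with_stock_knn_imputer(self, rng):
        """On the correlation-weighted matrix, a stock KNN imputer with
        uniform averaging reproduces the target column we impute."""
        from sklearn.impute import KNNImputer

        for _ in range(10):
            arr = rng.standard_normal((35, 5))
            for j in range(1, 5):
                arr[:, j] = rng.uniform(-1, 1) * arr[:, 0] + 0.4 * arr[:, j]
            arr[rng.choice(35, size=6, replace=False), 0] = np.nan
            df = pd.DataFrame({f"f{j}": arr[:, j] for j in range(5)})
            imp = WeightedKNNImputer("f0").fit(df)
            got = imp.transform(df)
            weighted = imp._weighted_rows(df)
            stock = KNNImputer(n_neighbors=10, weights="uniform")
            filled = stock.fit_transform(weighted)
            # dim 0 is the standardized weight-1 target; undo standardization
            expected = filled[:, 0] * imp.feature_stds_[0] + imp.feature_means_[0]
            assert np.allclose(got, expected, atol=1e-10)


class TestCrossGene:
    def fitted(self, rng, shift=0.0):
        arr = rng.standard_normal((25, 3))
        arr[:, 0] = arr[:, 1] * 2 + shift
        df = pd.DataFrame({f"f{j}": arr[:, j] for j in range(3)})
        return WeightedKNNImputer("f0").fit(df)

    def test_identical_imputers_mean_is_identity(self, rng):
        imp = self.fitted(rng)
        new = pd.DataFrame({"f0": [np.nan] * 8,
                            "f1": rng.standard_normal(8),
                            "f2": rng.standard_normal(8)})
        single = imp.predict_column(new)
        mean5 = CrossGeneImputer([imp] * 5).predict_column(new)
        assert np.allclose(single, mean5)

    def test_mean_of_distinct_predictions(self, rng):
        imps = [self.fitted(rng, shift=s) for s in (1.0, 2.0, 3.0, 4.0, 5.0)]
        new = pd.DataFrame({"f0": [np.nan] * 6,
                            "f1": rng.standard_normal(6),
                            "f2": rng.standard_normal(6)})
        preds = np.vstack([i.predict_column(new) for i in imps])
        got = impute_cross_gene(imps, table_from_array(
            np.column_stack([new["f0"], new["f1"], new["f2"]]), gene="H"))
        assert np.allclose(got, preds.mean(axis=0))

    def test_order_invariance(self, rng):
        imps = [self.fitted(rng, shift=s) for s in (0.0, 1.0, 2.0)]
        new = pd.DataFrame({"f0": [np.nan] * 5,
                            "f1": rng.standard_normal(5),
                            "f2": rng.standard_normal(5)})
        a = CrossGeneImputer(imps).predict_column(new)
        b = CrossGeneImputer(imps[::-1]).predict_column(new)
        assert np.allclose(a, b)

    def test_failing_imputer_skipped_with_warning(self, rng):
        good = self.fitted(rng)
        bad_df = pd.DataFrame({"f0": rng.standard_normal(25),
                               "g1": rng.standard_normal(25)})
        bad = WeightedKNNImputer("f0").fit(bad_df)  # helpers g1 absent later
        new = pd.DataFrame({"f0": [np.nan] * 4,
                            "f1": rng.standard_normal(4),
                            "f2": rng.standard_normal(4)})
        with pytest.warns(UserWarning, match="skipped"):
            got = CrossGeneImputer([good, bad]).predict_column(new)
        assert np.allclose(got, good.predict_column(new))

    def test_all_failing_raises(self, rng):
        bad_df = pd.DataFrame({"f0": rng.standard_normal(25),
                               "g1": rng.standard_normal(25)})
        bad = WeightedKNNImputer("f0").fit(bad_df)
        new = pd.DataFrame({"f0": [np.nan] * 4, "f1": np.zeros(4)})
        with pytest.raises(ValueError, match="all cross-gene"):
            with pytest.warns(UserWarning):
                CrossGeneImputer([bad]).predict_column(new)
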
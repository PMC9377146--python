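"""Metabolite preprocessing chain and downstream analyses."""

import numpy as np
import pandas as pd
import pytest

from mliome.metabolome import (MetaboliteTable, aggregate_bai,
                               batch_standardize, bile_log_ratio,
                               feature_prevalence_filter, iqr_filter,
                               knn_impute, log_quantile_normalize,
                               microbe_metabolite_correlations,
                               per_feature_models, quantile_normalize)
from mliome.stats import build_design


def _mtable(matrix, batches=None):
    df = pd.DataFrame(matrix, index=[f"f{i}" for i in range(len(matrix))])
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    b = pd.Series(batches, index=df.columns) if batches is not None else None
    return MetaboliteTable(df, batches=b)


class TestPrevalenceFilter:
    def test_strict_boundary(self):
        m = np.full((2, 10), np.nan)
        m[0, 0] = 5.0              # exactly 10% -> removed
        m[1, :2] = 5.0             # 20% -> retained
        out = feature_prevalence_filter(_mtable(m), 0.10)
        assert list(out.intensities.index) == ["f1"]

    def test_complete_feature_retained(self):
        out = feature_prevalence_filter(_mtable(np.ones((1, 5))), 0.10)
        assert out.intensities.shape == (1, 5)


class TestKnnImpute:
    def test_mean_of_two_nearest(self):
        # f0 missing at s2; f1/f2 identical to f0 elsewhere -> nearest
        m = np.array([
            [1.0, 2.0, np.nan],
            [1.0, 2.0, 4.0],
            [1.0, 2.0, 6.0],
            [50.0, 60.0, 70.0],
        ])
        out = knn_impute(_mtable(m), k=2)
        assert out.intensities.loc["f0", "s2"] == pytest.approx(5.0)

    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(0)
        m = _mtable(rng.uniform(1, 10, size=(6, 5)))
        assert knn_impute(m).intensities.equals(m.intensities)

    def test_entirely_missing_feature_rejected(self):
        m = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="entirely missing"):
            knn_impute(_mtable(m))

    def test_beats_feature_mean_imputation_under_mar(self):
        rng = np.random.default_rng(1)
        wins = 0
        n_rep = 50
        for _ in range(n_rep):
            base = rng.normal(0, 1, 30)
            truth = np.exp(base[None, :] + rng.normal(0, 0.3, (40, 30)))
            mask = rng.random(truth.shape) < 0.10
            mask[:, 0] = False  # keep every feature observed somewhere
            obs = np.where(mask, np.nan, truth)
            imputed = knn_impute(_mtable(obs), k=10).intensities.to_numpy()
            knn_err = np.sqrt(np.mean((imputed[mask] - truth[mask]) ** 2))
            fm = np.nanmean(obs, axis=1)
            mean_err = np.sqrt(np.mean(
                (np.broadcast_to(fm[:, None], truth.shape)[mask] - truth[mask]) ** 2))
            wins += knn_err < mean_err
        assert wins >= 0.9 * n_rep


class TestIqrFilter:
    def test_constant_feature_dropped_first(self):
        m = _mtable([[5.0] * 6, list(range(6)), [0, 9, 1, 8, 2, 7.0]])
        out = iqr_filter(m, keep_fraction=2 / 3)
        assert "f0" not in out.intensities.index

    def test_keep_all(self):
        m = _mtable([[1.0, 2], [5.0, 9]])
        assert iqr_filter(m, keep_fraction=1.0).intensities.equals(m.intensities)

    def test_two_feature_ordering(self):
        m = _mtable([[0.0, 5.0, 2.5, 1.0], [2.0, 3.0, 2.5, 2.2]])
        out = iqr_filter(m, keep_fraction=0.5)
        assert list(out.intensities.index) == ["f0"]

    def test_small_table_untouched_by_default_rule(self):
        m = _mtable(np.arange(20.0).reshape(4, 5))
        assert iqr_filter(m).intensities.shape == (4, 5)


class TestQuantileNormalize:
    def test_two_sample_worked_example(self):
        m = _mtable(np.exp([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = log_quantile_normalize(m)
        assert np.allclose(out.intensities["s0"], [2.5, 3.5, 4.5])
        assert np.allclose(out.intensities["s1"], [2.5, 3.5, 4.5])

    def test_identical_samples_unchanged(self):
        m = _mtable(np.exp([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0]]))
        out = log_quantile_normalize(m)
        assert np.allclose(out.intensities, np.log(m.intensities))

    def test_sorted_profiles_identical_and_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 8)))
        q1 = quantile_normalize(df)
        sorted_cols = np.sort(q1.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])
        q2 = quantile_normalize(q1)
        assert np.allclose(q1, q2)

    def test_nonpositive_entry_named(self):
        m = _mtable([[1.0, 0.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="f0.*s1"):
            log_quantile_normalize(m)


class TestBatchStandardize:
    def test_single_batch_identity(self):
        rng = np.random.default_rng(3)
        m = _mtable(rng.uniform(1, 5, (4, 6)), batches=["b1"] * 6)
        out = batch_standardize(m)
        assert np.allclose(out.intensities, m.intensities)

    def test_planted_shift_removed(self):
        rng = np.random.default_rng(4)
        n_feat, per_batch = 60, 20
        base = rng.normal(10, 1, (n_feat, 2 * per_batch))
        base[:, per_batch:] += 2.0  # batch shift
        m = _mtable(base, batches=["b1"] * per_batch + ["b2"] * per_batch)
        out = batch_standardize(m)
        from scipy import stats as sps

        n_removed = 0
        for f in out.intensities.index:
            a = out.intensities.loc[f][:per_batch]
            b = out.intensities.loc[f][per_batch:]
            if sps.f_oneway(a, b).pvalue > 0.05:
                n_removed += 1
        assert n_removed >= 0.95 * n_feat

    def test_commutes_with_feature_reordering(self):
        rng = np.random.default_rng(5)
        m = _mtable(rng.normal(5, 1, (6, 8)), batches=["b1"] * 4 + ["b2"] * 4)
        out = batch_standardize(m)
        rev = MetaboliteTable(m.intensities.iloc[::-1], batches=m.batches)
        out_rev = batch_standardize(rev)
        assert np.allclose(out.intensities.iloc[::-1], out_rev.intensities)

    def test_single_sample_batch_rejected(self):
        m = _mtable(np.ones((2, 3)), batches=["b1", "b1", "b2"])
        with pytest.raises(ValueError, match="single sample"):
            batch_standardize(m)


class TestPerFeatureModels:
    def _design(self, n, rng):
        meta = pd.DataFrame({
            "gender": rng.choice(["female", "male"], n),
            "dx": ["CD"] * (n // 2) + ["nonIBD"] * (n // 2),
        }, index=[f"s{j}" for j in range(n)])
        return build_design(meta, ["gender", "dx"])

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(6)
        n = 60
        X = rng.normal(size=(30, n))
        X[:5, : n // 2] += 3.0
        m = _mtable(X)
        res = per_feature_models(m, self._design(n, rng), "dx")
        assert (res["q"].iloc[:5] < 0.05).all()

    def test_term_absent_rejected(self):
        rng = np.random.default_rng(7)
        m = _mtable(rng.normal(size=(3, 10)))
        with pytest.raises(Exception, match="term"):
            per_feature_models(m, self._design(10, rng), "age")


class TestBileRatio:
    def test_equal_and_tenfold(self):
        m = _mtable([[100.0, 100.0], [100.0, 10.0]])
        r = bile_log_ratio(m, "f0", "f1")
        assert r["s0"] == pytest.approx(0.0)
        assert r["s1"] == pytest.approx(np.log(10))

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(8)
        m = _mtable(rng.uniform(10, 100, (2, 6)))
        a = bile_log_ratio(m, "f0", "f1")
        b = bile_log_ratio(m, "f1", "f0")
        assert np.allclose(a, -b)

    def test_missing_feature_id_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            bile_log_ratio(_mtable([[1.0]]), "f0", "nope")


class TestAggregateBai:
    def _ko(self, values):
        from mliome.metabolome import BAI_KOS

        return pd.DataFrame(values, index=list(BAI_KOS),
                            columns=["s0"])

    def test_sum_of_six(self):
        assert aggregate_bai(self._ko([[1e-4]] * 6))["s0"] == pytest.approx(6e-4)

    def test_row_order_invariant(self):
        ko = self._ko([[1e-4], [2e-4], [3e-4], [0.0], [0.0], [4e-4]])
        assert aggregate_bai(ko.iloc[::-1])["s0"] == aggregate_bai(ko)["s0"]

    def test_absent_kos_contribute_zero_and_all_absent_error(self):
        ko = self._ko([[1e-4]] * 6).iloc[:2]
        assert aggregate_bai(ko)["s0"] == pytest.approx(2e-4)
        other = pd.DataFrame([[0.5]], index=["K00001"], columns=["s0"])
        with pytest.raises(ValueError, match="none of the bai"):
            aggregate_bai(other)


class TestMicrobeMetaboliteCorrelations:
    def test_monotone_pair_perfect_rho(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        microbes = pd.DataFrame([x], index=["t0"],
                                columns=[f"s{j}" for j in range(20)])
        mets = pd.DataFrame([np.exp(x)], index=["f0"], columns=microbes.columns)
        res = microbe_metabolite_correlations(microbes, mets)
        assert res.loc[0, "rho"] == pytest.approx(1.0)

    def test_symmetry_in_roles(self):
        rng = np.random.default_rng(10)
        a = pd.DataFrame(rng.normal(size=(2, 15)), index=["t0", "t1"],
                         columns=[f"s{j}" for j in range(15)])
        b = pd.DataFrame(rng.normal(size=(2, 15)), index=["f0", "f1"],
                         columns=a.columns)
        r1 = microbe_metabolite_correlations(a, b)
        r2 = microbe_metabolite_correlations(b, a)
        m1 = r1.set_index(["taxon", "metabolite"])["rho"]
        m2 = r2.set_index(["metabolite", "taxon"])["rho"]
        for (t, f), rho in m1.items():
            assert rho == pytest.approx(m2[(t, f)])

    def test_no_shared_samples_rejected(self):
        a = pd.DataFrame([[1.0]], index=["t0"], columns=["s0"])
        b = pd.DataFrame([[1.0]], index=["f0"], columns=["s1"])
        with pytest.raises(ValueError, match="shared"):
            microbe_metabolite_correlations(a, b)
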
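"""Differential abundance: size factors, dispersions, Wald tests, dysbiosis."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from mliome.da import (DAResult, TaxonSets, dysbiosis_index, fit_dispersions,
                       nb_wald_test, prevalence_filter, significant_sets,
                       size_factors)
from mliome.diversity import CountTable
from mliome.stats import build_design


def _table(matrix, **meta):
    counts = pd.DataFrame(matrix, index=[f"t{i}" for i in range(len(matrix))])
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    n = counts.shape[1]
    samples = pd.DataFrame({
        "subject_id": [f"subj{j}" for j in range(n)],
        "site": ["cecum"] * n,
        **meta,
    }, index=counts.columns)
    return CountTable(counts, samples)


class TestPrevalenceFilter:
    def test_boundary_rule(self):
        m = np.zeros((2, 100), dtype=int)
        m[0, :24] = 5   # 24% -> removed
        m[1, :25] = 5   # 25% -> retained
        out = prevalence_filter(_table(m), 0.25)
        assert list(out.counts.index) == ["t1"]

    def test_threshold_epsilon_keeps_all(self):
        t = _table([[1, 0], [0, 1]])
        assert prevalence_filter(t, 1e-9).counts.shape == (2, 2)

    def test_everything_removed_is_error(self):
        with pytest.raises(ValueError, match="every taxon"):
            prevalence_filter(_table([[1, 0, 0, 0]]), 0.5)


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9], "b": [5, 9], "c": [5, 9]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, size=(30, 4)),
                              columns=list("abcd"))
        sf = size_factors(counts)
        counts2 = counts.copy()
        counts2["b"] *= 5
        sf2 = size_factors(counts2)
        # ratios to the other samples scale by 5 (up to global rescale)
        assert sf2["b"] / sf2["a"] == pytest.approx(5 * sf["b"] / sf["a"], rel=1e-9)

    def test_robust_to_added_constant_taxon(self):
        # a depth-uninformative taxon (ratio 1 everywhere) can move each
        # sample's median element by at most one position, so factors move
        # only slightly; exact invariance does not hold for a median
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 100, size=(20, 5)))
        plus = pd.concat([counts, pd.DataFrame([[7] * 5], index=[99])])
        assert np.allclose(size_factors(counts), size_factors(plus), rtol=0.10)


def _nb_negloglik_full(params, y, X, offset, alpha):
    mu = np.exp(X @ params + offset)
    r = 1.0 / alpha
    ll = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return -ll.sum()


class TestNbWald:
    def _simulate(self, rng, n_taxa=6, n=12, log2fc=None):
        group = np.repeat([0, 1], n // 2)
        mu0 = rng.uniform(20, 200, n_taxa)
        alpha = 0.2
        counts = np.empty((n_taxa, n), dtype=int)
        fc = np.zeros(n_taxa) if log2fc is None else np.asarray(log2fc, float)
        for i in range(n_taxa):
            mu = mu0[i] * 2.0 ** (fc[i] * group)
            counts[i] = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        t = _table(counts, dx=np.where(group, "CD", "nonIBD"))
        return t

    def test_coefficients_match_bruteforce_mle(self):
        """NB regression vs direct likelihood maximization, same dispersion."""
        rng = np.random.default_rng(2)
        t = self._simulate(rng, log2fc=[0, 0, 2, -2, 0, 1])
        design = build_design(t.metadata_for_samples(), ["dx"])
        sf = size_factors(t.counts)
        disp = pd.Series(0.2, index=t.counts.index)
        res = nb_wald_test(t.counts, design, "dx", sf=sf, dispersions=disp)
        X = design.matrix.to_numpy(float)
        offset = np.log(sf.to_numpy())
        for taxon in t.counts.index:
            y = t.counts.loc[taxon].to_numpy(float)
            opt = optimize.minimize(
                _nb_negloglik_full, x0=np.array([np.log(y.mean() + 1), 0.0]),
                args=(y, X, offset, 0.2), method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
            )
            l2fc_oracle = opt.x[1] / np.log(2)
            assert res.table.loc[taxon, "log2fc"] == pytest.approx(
                l2fc_oracle, abs=1e-4)

    def test_planted_effect_signs_recovered(self):
        rng = np.random.default_rng(3)
        t = self._simulate(rng, n_taxa=10, n=60,
                           log2fc=[3, 3, -3, -3, 0, 0, 0, 0, 0, 0])
        design = build_design(t.metadata_for_samples(), ["dx"])
        res = nb_wald_test(t.counts, design, "dx")
        fc = res.table["log2fc"]
        assert (fc.iloc[:2] > 0).all()
        assert (fc.iloc[2:4] < 0).all()

    def test_constant_term_rejected(self):
        rng = np.random.default_rng(4)
        t = self._simulate(rng)
        t.samples["dx"] = "CD"
        design_meta = t.metadata_for_samples()
        with pytest.raises(Exception, match="constant"):
            design = build_design(design_meta, ["dx"])
            nb_wald_test(t.counts, design, "dx")

    def test_matches_pydeseq2_fold_changes(self):
        """Independent route: DESeq2 (pydeseq2) on the same instance."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(5)
        t = self._simulate(rng, n_taxa=25, n=40,
                           log2fc=[2] * 5 + [-2] * 5 + [0] * 15)
        design = build_design(t.metadata_for_samples(), ["dx"])
        ours = nb_wald_test(t.counts, design, "dx")

        meta = t.metadata_for_samples()[["dx"]].copy()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=t.counts.T, metadata=meta,
                               design="~dx", quiet=True)
            dds.deseq2()
            stats = DeseqStats(dds, contrast=["dx", "nonIBD", "CD"], quiet=True)
            stats.summary()
        theirs = -stats.results_df["log2FoldChange"]  # flip to CD-vs-control
        r = np.corrcoef(ours.table["log2fc"], theirs.loc[ours.table.index])[0, 1]
        assert r > 0.95
        planted = ours.table.index[:10]
        assert (np.sign(ours.table.loc[planted, "log2fc"])
                == np.sign(theirs.loc[planted])).all()


class TestFitDispersions:
    def test_poisson_limit_small_dispersion(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.poisson(80, size=(40, 60)))
        counts.columns = [f"s{j}" for j in range(60)]
        meta = pd.DataFrame({"dx": ["CD", "nonIBD"] * 30}, index=counts.columns)
        design = build_design(meta, ["dx"])
        disp = fit_dispersions(counts, design, size_factors(counts),
                               shrinkage_weight=0.0)
        assert disp["dispersion"].median() < 0.05

    def test_full_shrinkage_collapses_to_trend(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(
            rng.negative_binomial(2, 0.05, size=(30, 40)))
        counts.columns = [f"s{j}" for j in range(40)]
        meta = pd.DataFrame({"dx": ["CD", "nonIBD"] * 20}, index=counts.columns)
        design = build_design(meta, ["dx"])
        disp = fit_dispersions(counts, design, size_factors(counts),
                               shrinkage_weight=1.0)
        ok = disp[disp["fit_ok"]]
        assert np.allclose(ok["dispersion"], ok["alpha_trend"], rtol=1e-8)

    def test_known_dispersion_recovered(self):
        rng = np.random.default_rng(8)
        alpha = 0.5
        mu = rng.uniform(50, 500, 60)
        counts = pd.DataFrame(
            rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu[:, None]),
                                  size=(60, 100)))
        counts.columns = [f"s{j}" for j in range(100)]
        meta = pd.DataFrame({"dx": ["CD", "nonIBD"] * 50}, index=counts.columns)
        design = build_design(meta, ["dx"])
        disp = fit_dispersions(counts, design, size_factors(counts))
        med = disp["dispersion"].median()
        assert 0.35 <= med <= 0.65


class TestSignificantSetsAndIndex:
    def _da(self, q, l2fc, abund):
        table = pd.DataFrame({
            "log2fc": l2fc, "p": q, "q": q, "mean_norm_rel_abund": abund,
            "dispersion": 0.1, "converged": True,
        }, index=[f"t{i}" for i in range(len(q))])
        return DAResult(table=table, term="dx", design_columns=[])

    def test_abundance_filter_excludes(self):
        da = self._da([0.04], [2.0], [1e-6])
        s = significant_sets(da)
        assert not s.enriched and not s.depleted

    def test_grs_threshold_includes_q_008(self):
        da = self._da([0.08], [1.5], [1e-3])
        assert significant_sets(da, q_threshold=0.1).enriched == {"t0"}
        assert significant_sets(da, q_threshold=0.05).enriched == set()

    def test_all_null_empty_sets(self):
        da = self._da([1.0, 1.0], [1.0, -1.0], [1e-3, 1e-3])
        s = significant_sets(da)
        assert not s.enriched and not s.depleted

    def test_index_definition_and_antisymmetry(self):
        rel = pd.DataFrame({"x": [0.2, 0.1, 0.7]}, index=["e", "d", "o"])
        sets = TaxonSets({"e"}, {"d"})
        res = dysbiosis_index(rel, sets, pseudocount=1e-12)
        assert res.values["x"] == pytest.approx(np.log(2), abs=1e-9)
        swapped = dysbiosis_index(rel, sets.swapped(), pseudocount=1e-12)
        assert swapped.values["x"] == pytest.approx(-res.values["x"], abs=1e-9)

    def test_equal_sums_zero_and_guard(self):
        rel = pd.DataFrame({"x": [0.3, 0.3, 0.0]}, index=["e", "d", "z"])
        assert dysbiosis_index(rel, TaxonSets({"e"}, {"d"})).values["x"] == \
            pytest.approx(0.0)
        res = dysbiosis_index(rel, TaxonSets({"e"}, {"z"}), pseudocount=1e-6)
        assert np.isfinite(res.values["x"])
        with pytest.raises(ValueError, match="empty"):
            dysbiosis_index(rel, TaxonSets(set(), set()))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TaxonSets({"a"}, {"a"})
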
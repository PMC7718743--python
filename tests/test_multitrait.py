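"""Bivariate GBLUP, selection index, and the missing-rate experiment."""

import numpy as np
import pandas as pd
import pytest

import orchardgs as og
from orchardgs.cv import make_partition, prediction_accuracy
from orchardgs.multitrait import (BivariateGBLUP, missing_rate_experiment,
                                  model_based_index, predict_with_pheno_proxy)
from orchardgs.wgr import GBLUP


def _genotype_trait(design_seed, rg, h2=(0.6, 0.6), n_progeny=300):
    corr = np.array([[1.0, rg], [rg, 1.0]])
    # enough pleiotropic loci that the realized TBV correlation stays close
    # to the target (sampling sd of the effect correlation ~ 1/sqrt(n_qtl))
    arch = og.TraitArchitecture(traits=("a", "b"), h2_target=h2,
                                genetic_corr=corr, n_qtl=80)
    design = og.CrossDesign(seed=design_seed, n_progeny=n_progeny,
                            n_chrom=4, markers_per_chrom=60)
    geno, pheno, truth = og.simulate_population(design, arch)
    gm = pheno.pivot_table(index="genotype", columns="trait", values="value")
    return og.compute_grm(geno), gm["a"], gm["b"], truth


class TestBivariateGBLUP:
    def test_duplicated_trait_has_unit_genetic_correlation(
            self, bivariate_population):
        _, y1, _, A, _ = bivariate_population
        fit = BivariateGBLUP(y1, y1.copy(), A).fit()
        assert 0.98 <= fit.genetic_correlation <= 1.0 + 1e-9

    def test_genetic_correlation_recovery(self):
        ests = []
        for seed in range(20):
            A, y1, y2, _ = _genotype_trait(800 + seed, rg=0.8)
            ests.append(BivariateGBLUP(y1, y2, A).fit().genetic_correlation)
        assert abs(np.mean(ests) - 0.8) < 0.2

    def test_independent_traits_show_weak_correlation(self):
        small = 0
        n_seeds = 20
        for seed in range(n_seeds):
            A, y1, y2, _ = _genotype_trait(900 + seed, rg=0.0)
            rg = BivariateGBLUP(y1, y2, A).fit().genetic_correlation
            small += abs(rg) < 0.3
        assert small / n_seeds >= 0.9

    def test_diagonal_fit_reproduces_univariate(self, bivariate_population):
        _, y1, y2, A, _ = bivariate_population
        fit = BivariateGBLUP(y1, y2, A).fit(diag_only=True)
        uni = GBLUP(y1, A).fit()
        assert np.allclose(fit.genetic_values["trait1"].to_numpy(), uni.g,
                           atol=1e-6)

    def test_nesting_bivariate_loglik_not_worse(self, bivariate_population):
        _, y1, y2, A, _ = bivariate_population
        full = BivariateGBLUP(y1, y2, A).fit()
        diag = BivariateGBLUP(y1, y2, A).fit(diag_only=True)
        assert full.loglik >= diag.loglik - 1e-6

    def test_trait_label_symmetry(self, bivariate_population):
        _, y1, y2, A, _ = bivariate_population
        f12 = BivariateGBLUP(y1, y2, A).fit()
        f21 = BivariateGBLUP(y2, y1, A).fit()
        assert np.allclose(f12.genetic_values["trait1"],
                           f21.genetic_values["trait2"], atol=1e-4)
        assert f12.genetic_correlation == pytest.approx(
            f21.genetic_correlation, abs=1e-4)

    def test_constant_traits_rejected(self, bivariate_population):
        _, y1, _, A, _ = bivariate_population
        const = pd.Series(1.0, index=y1.index)
        with pytest.raises(ValueError):
            BivariateGBLUP(const, const, A)

    def test_summary_mentions_genetic_correlation(self, bivariate_population):
        _, y1, y2, A, _ = bivariate_population
        text = BivariateGBLUP(y1, y2, A).fit().summary()
        assert "r_g" in text and "Sigma_u" in text


class TestModelBasedIndex:
    def test_zero_variance_proxy_reduces_to_gblup(self, bivariate_population):
        geno, y1, _, A, _ = bivariate_population
        ids = A.A.index
        train = ids[:110]
        flat = pd.Series(0.0, index=ids)
        with pytest.warns(UserWarning, match="zero-variance"):
            idx = model_based_index(y1, flat, A, train)
        ti = ids.get_indexer(train)
        from orchardgs._reml import reml_kernel
        from scipy import linalg
        Kv = A.A.to_numpy()
        r = reml_kernel(y1.reindex(train).to_numpy(), Kv[np.ix_(ti, ti)])
        alpha = linalg.solve(Kv[np.ix_(ti, ti)]
                             + r.delta * np.eye(len(train)), r.resid)
        assert np.allclose(idx.to_numpy(), Kv[:, ti] @ alpha, atol=1e-6)

    def test_self_proxy_does_not_hurt(self):
        # proxy trait = focal trait at high heritability: the index should
        # at least match univariate GBLUP accuracy
        A, y1, _, _ = _genotype_trait(41, rg=0.9, h2=(0.9, 0.9),
                                      n_progeny=250)
        ids = A.A.index
        Kv = A.A.to_numpy()
        from orchardgs._reml import reml_kernel
        from scipy import linalg
        rng = np.random.default_rng(6)
        d_uni, d_idx = [], []
        for rep in range(100):
            train, val = make_partition(ids, 0.75, rng.integers(2 ** 31))
            ti, vi = ids.get_indexer(train), ids.get_indexer(val)
            r = reml_kernel(y1.reindex(train).to_numpy(), Kv[np.ix_(ti, ti)])
            alpha = linalg.solve(Kv[np.ix_(ti, ti)]
                                 + r.delta * np.eye(len(train)), r.resid)
            gebv_all = pd.Series(Kv[:, ti] @ alpha, index=ids)
            yv = y1.reindex(val).to_numpy()
            d_uni.append(prediction_accuracy(gebv_all.iloc[vi], yv))
            idx = model_based_index(y1.reindex(train), gebv_all, A, train)
            d_idx.append(prediction_accuracy(idx.iloc[vi], yv))
        assert np.mean(d_idx) >= np.mean(d_uni) - 0.01

    def test_uncorrelated_proxy_roughly_neutral(self):
        A, y1, y2, _ = _genotype_trait(43, rg=0.0, h2=(0.5, 0.9),
                                       n_progeny=250)
        ids = A.A.index
        Kv = A.A.to_numpy()
        from orchardgs._reml import reml_kernel
        from scipy import linalg
        rng = np.random.default_rng(7)
        d_uni, d_idx = [], []
        for rep in range(100):
            train, val = make_partition(ids, 0.75, rng.integers(2 ** 31))
            ti, vi = ids.get_indexer(train), ids.get_indexer(val)
            r = reml_kernel(y1.reindex(train).to_numpy(), Kv[np.ix_(ti, ti)])
            alpha = linalg.solve(Kv[np.ix_(ti, ti)]
                                 + r.delta * np.eye(len(train)), r.resid)
            yv = y1.reindex(val).to_numpy()
            d_uni.append(prediction_accuracy(Kv[np.ix_(vi, ti)] @ alpha, yv))
            rp = reml_kernel(y2.reindex(train).to_numpy(), Kv[np.ix_(ti, ti)])
            ap = linalg.solve(Kv[np.ix_(ti, ti)]
                              + rp.delta * np.eye(len(train)), rp.resid)
            proxy = pd.Series(Kv[:, ti] @ ap, index=ids)
            idx = model_based_index(y1.reindex(train), proxy, A, train)
            d_idx.append(prediction_accuracy(idx.iloc[vi], yv))
        assert abs(np.mean(d_idx) - np.mean(d_uni)) <= 0.05


class TestPhenoProxy:
    def test_strong_genetic_correlation_helps(self):
        A, y1, y2, _ = _genotype_trait(47, rg=0.9, h2=(0.45, 0.9),
                                       n_progeny=200)
        ids = A.A.index
        Kv = A.A.to_numpy()
        from orchardgs._reml import reml_kernel
        from scipy import linalg
        rng = np.random.default_rng(8)
        wins = 0
        n_rep = 50
        for rep in range(n_rep):
            train, val = make_partition(ids, 0.75, rng.integers(2 ** 31))
            ti, vi = ids.get_indexer(train), ids.get_indexer(val)
            yv = y1.reindex(val).to_numpy()
            r = reml_kernel(y1.reindex(train).to_numpy(), Kv[np.ix_(ti, ti)])
            alpha = linalg.solve(Kv[np.ix_(ti, ti)]
                                 + r.delta * np.eye(len(train)), r.resid)
            acc_uni = prediction_accuracy(Kv[np.ix_(vi, ti)] @ alpha, yv)
            biv = predict_with_pheno_proxy(y1.reindex(train), y2, A, train)
            acc_biv = prediction_accuracy(biv.iloc[vi], yv)
            wins += acc_biv > acc_uni
        assert wins / n_rep >= 0.8

    def test_decoupled_covariance_equals_univariate(
            self, bivariate_population):
        geno, y1, y2, A, _ = bivariate_population
        ids = A.A.index
        train = ids[:110]
        masked = y1.reindex(ids).copy()
        masked[~ids.isin(train)] = np.nan
        fit = BivariateGBLUP(masked, y2, A).fit(diag_only=True)
        from orchardgs._reml import reml_kernel
        from scipy import linalg
        Kv = A.A.to_numpy()
        ti = ids.get_indexer(train)
        r = reml_kernel(y1.reindex(train).to_numpy(), Kv[np.ix_(ti, ti)])
        alpha = linalg.solve(Kv[np.ix_(ti, ti)]
                             + r.delta * np.eye(len(train)), r.resid)
        assert np.allclose(fit.genetic_values["trait1"].to_numpy(),
                           Kv[:, ti] @ alpha, atol=1e-6)


class TestMissingRateExperiment:
    def test_rate_zero_matches_unmasked_runs(self, bivariate_population):
        _, y1, y2, A, _ = bivariate_population
        ids = A.A.index
        report = missing_rate_experiment(y1, y2, A, rates=(0.0,), n_reps=2,
                                         seed=99)
        # reproduce the partitions the experiment drew
        rng = np.random.default_rng(99)
        for rep in range(2):
            train, val = make_partition(ids, 0.75, rng.integers(2 ** 31))
            rng.choice(train, size=len(train), replace=False)  # kept-draw
            vi = ids.get_indexer(val)
            yv = y1.reindex(val).to_numpy()
            biv = predict_with_pheno_proxy(y1.reindex(train), y2, A, train)
            expected = prediction_accuracy(biv.iloc[vi], yv)
            got = report.records.query(
                "replicate == @rep and method == 'multi_trait'")[
                "accuracy"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_extreme_rate_skipped_with_warning(self, bivariate_population):
        _, y1, y2, A, _ = bivariate_population
        with pytest.warns(UserWarning, match="skipped"):
            report = missing_rate_experiment(y1, y2, A, rates=(0.99,),
                                             n_reps=1, seed=1)
        assert report.records.empty

    def test_structure_and_methods(self, bivariate_population):
        _, y1, y2, A, _ = bivariate_population
        report = missing_rate_experiment(y1, y2, A, rates=(0.0, 0.5),
                                         n_reps=3, seed=2)
        assert set(report.records["method"]) == {
            "univariate", "multi_trait", "model_based_index"}
        assert set(report.records["rate"]) == {0.0, 0.5}
        assert report.records["accuracy"].between(-1, 1).all()
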
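"""Canned desk-scale experiments exercising the full pipeline.

Each function simulates one or more F1 pseudo-testcross populations at the
study's dimensions (153 progeny, 8 chromosomes; 640 SNPs except where a
denser panel is the point), runs the relevant models, and returns the
summary quantities.  They back the acceptance checks and are convenient
entry points for exploring the methods.

All randomness flows from a single seed through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

from . import (CrossDesign, GenotypeMatrix, TraitArchitecture,
               adjust_all_traits, compute_grm, simulate_population)
from ._reml import reml_kernel
from .cv import CVConfig, GSData, make_partition, prediction_accuracy, \
    run_scenario, summarize
from .multitrait import missing_rate_experiment, model_based_index, \
    predict_with_pheno_proxy
from .qtl import genome_scan, permutation_threshold
from .wgr import BayesianAlphabet, ChainSettings, GBLUP, RidgeBLUP

__all__ = ["model_equivalence", "sampler_vs_ridge", "h2_recovery",
           "scan_type1_rate", "tp_size_sweep", "marker_density_sweep",
           "qtl_fixed_experiment", "multitrait_experiment"]


def _seeds(seed, n):
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _population(seed, *, h2=0.7, n_qtl=30, major_share=0.0,
                markers_per_chrom=80, adjust=True):
    design = CrossDesign(seed=seed, markers_per_chrom=markers_per_chrom)
    arch = TraitArchitecture(traits=("T",), h2_target=h2, n_qtl=n_qtl,
                             major_qtl_share=major_share)
    geno, pheno, truth = simulate_population(design, arch)
    if adjust:
        adjusted, _ = adjust_all_traits(pheno)
        return geno, adjusted, truth
    return geno, pheno, truth


def model_equivalence(seed: int) -> float:
    """Correlation between RR-BLUP and GBLUP GEBVs on 153 x 640 markers.

    The two models are marker-equivalent; this checks the REML/BLUP
    plumbing end to end (expected > 0.9999).
    """
    geno, adjusted, _ = _population(seed)
    y = adjusted["T"]
    rr = RidgeBLUP(y, geno.dosage).fit()
    gb = GBLUP(y, compute_grm(geno)).fit()
    return float(np.corrcoef(rr.g, gb.g)[0, 1])


def sampler_vs_ridge(seed: int, n_iter: int = 20_000) -> float:
    """BRR with fixed variances against the closed-form ridge solution.

    With the variance updates switched off, the Gibbs sampler's posterior
    mean effect vector must converge to the ridge estimate at
    lambda = sigma_e^2/sigma_u^2 (expected correlation > 0.999).
    """
    geno, adjusted, _ = _population(seed)
    y = adjusted["T"]
    ref = RidgeBLUP(y, geno.dosage).fit()
    chain = ChainSettings(n_iter=n_iter, burn_in=n_iter // 5, thin=2,
                          seed=_seeds(seed, 1)[0])
    brr = BayesianAlphabet(y, geno.dosage, model="BRR",
                           sigma_u2=ref.sigma_u2, sigma_e2=ref.sigma_e2,
                           chain=chain).fit()
    Zc = geno.dosage.to_numpy(float)
    Zc = Zc - Zc.mean(axis=0)
    ridge = RidgeBLUP(y, Zc).fit(delta=ref.sigma_e2 / ref.sigma_u2)
    return float(np.corrcoef(brr.u, ridge.u)[0, 1])


def h2_recovery(seed: int, targets=(0.2, 0.5, 0.8),
                n_seeds: int = 20) -> dict:
    """GBLUP REML heritability estimates against simulated targets.

    Phenotypes are genotype-level values (TBV + noise at the target h2);
    the estimate is sigma_u^2 mean(diag A) / (sigma_u^2 mean(diag A) +
    sigma_e^2), the genomic variance on the observed scale.
    Returns target -> mean estimate over ``n_seeds`` populations.
    """
    out = {}
    child = _seeds(seed, n_seeds * len(targets))
    k = 0
    for h2 in targets:
        ests = []
        for _ in range(n_seeds):
            s = child[k]
            k += 1
            design = CrossDesign(seed=s)
            arch = TraitArchitecture(traits=("T",), h2_target=h2, n_qtl=100)
            geno, _, truth = simulate_population(design, arch)
            tbv = truth.true_breeding_values["T"].to_numpy()
            rng = np.random.default_rng(s + 1)
            y = tbv + rng.normal(0, np.sqrt(np.var(tbv) * (1 - h2) / h2),
                                 tbv.size)
            grm = compute_grm(geno)
            fit = GBLUP(y, grm).fit()
            scale = float(np.mean(np.diag(grm.values)))
            vg = fit.sigma_u2 * scale
            ests.append(vg / (vg + fit.sigma_e2))
        out[h2] = float(np.mean(ests))
    return out


def scan_type1_rate(seed: int, n_traits: int = 200, n_perm: int = 200,
                    alpha: float = 0.01) -> float:
    """Genome-wide type-I error of the permutation-thresholded scan.

    Null traits (pure noise) scanned against their own permutation
    thresholds; the genome-wide rejection rate should sit near alpha.
    """
    geno, _, _ = _population(seed, adjust=False)
    rng = np.random.default_rng(_seeds(seed, 1)[0])
    rejections = 0
    for i in range(n_traits):
        y = rng.normal(size=geno.n_individuals)
        thr = permutation_threshold(y, geno, n_perm=n_perm, alpha=alpha,
                                    seed=int(rng.integers(2 ** 31)))
        scan = genome_scan(y, geno)
        rejections += bool(scan.lod.max() > thr)
    return rejections / n_traits


def tp_size_sweep(seed: int, n_reps: int = 100,
                  sizes=(43, 76, 115)) -> dict:
    """Mean RR-BLUP accuracy at training-population sizes 43/76/115."""
    geno, adjusted, _ = _population(seed, h2=0.6, n_qtl=30, major_share=0.3)
    data = GSData(geno=geno, phenos=adjusted)
    cfg = CVConfig(trait="T", scenario="tp_size", n_replicates=n_reps,
                   seed=_seeds(seed, 1)[0], tp_sizes=tuple(sizes))
    out = summarize(run_scenario(cfg, data))
    return {int(r.tp_size): float(r.mean) for r in out.itertuples()}


def marker_density_sweep(seed: int, n_reps: int = 100) -> dict:
    """Mean RR-BLUP accuracy over marker subsets of a dense panel.

    Uses an 8 x 400 = 3,200-SNP panel so that, like the study's full
    panel, prediction saturates well below 100% density; subsets are
    50 and 100 SNPs plus 10%, 50% and 100% of the panel.
    """
    geno, adjusted, _ = _population(seed, h2=0.6, n_qtl=30, major_share=0.3,
                                    markers_per_chrom=400)
    data = GSData(geno=geno, phenos=adjusted)
    cfg = CVConfig(trait="T", scenario="marker_density", n_replicates=n_reps,
                   seed=_seeds(seed, 1)[0], marker_numbers=(50, 100),
                   marker_fractions=(0.10, 0.50, 1.0))
    out = summarize(run_scenario(cfg, data))
    return {int(r.n_markers): float(r.mean) for r in out.itertuples()}


def qtl_fixed_experiment(seed: int, n_truths: int = 5,
                         reps_per_truth: int = 20) -> dict:
    """Fold-wise QTL-as-fixed-covariates model against the baseline.

    Two trait archetypes at h2 = 0.6: one carrying a major QTL (50% of
    genetic variance) and one with no major QTL (30 modest loci).  Means
    are taken over ``n_truths`` independent populations x
    ``reps_per_truth`` cross-validation replicates each.
    Returns mean accuracies keyed by (archetype, method).
    """
    child = _seeds(seed, 2 * n_truths)
    out = {}
    for label, share, n_qtl, seeds in (
            ("major", 0.5, 40, child[:n_truths]),
            ("polygenic", 0.0, 30, child[n_truths:])):
        base, fixed = [], []
        for s in seeds:
            geno, adjusted, _ = _population(s, h2=0.6, n_qtl=n_qtl,
                                            major_share=share)
            data = GSData(geno=geno, phenos=adjusted)
            cfg = CVConfig(trait="T", scenario="qtl_fixed",
                           n_replicates=reps_per_truth, seed=s + 1)
            rec = run_scenario(cfg, data).records
            base.append(rec.loc[rec.method == "baseline", "accuracy"].mean())
            fixed.append(rec.loc[rec.method == "qtl_fixed",
                                 "accuracy"].mean())
        out[label] = {"baseline": float(np.mean(base)),
                      "qtl_fixed": float(np.mean(fixed))}
    return out


def _bivariate_population(seed):
    corr = np.array([[1.0, 0.8], [0.8, 1.0]])
    arch = TraitArchitecture(traits=("focal", "proxy"),
                             h2_target=(0.45, 0.9), n_qtl=40,
                             genetic_corr=corr)
    design = CrossDesign(seed=seed)
    geno, pheno, _ = simulate_population(design, arch)
    adjusted, _ = adjust_all_traits(pheno)
    return compute_grm(geno), adjusted["focal"], adjusted["proxy"]


def multitrait_experiment(seed: int, n_truths: int = 2,
                          reps_per_truth: int = 50) -> dict:
    """Trait-assisted prediction under a 0.8 genetic correlation.

    Measures (i) the model-based selection index against univariate GBLUP
    on fully phenotyped training sets and (ii) the bivariate model against
    univariate GBLUP when 90% of the focal training phenotypes are
    missing.  Focal trait h2 = 0.45, proxy h2 = 0.9 (an easy, heritable
    proxy such as soluble-solids content standing in for a costly trait).
    """
    child = _seeds(seed, n_truths)
    uni, idx, uni90, biv90 = [], [], [], []
    for s in child:
        A, y_focal, y_proxy = _bivariate_population(s)
        ids = A.A.index
        Kv = A.A.to_numpy()
        rng = np.random.default_rng(s + 7)
        for rep in range(reps_per_truth):
            train, val = make_partition(ids, 0.75, rng.integers(2 ** 31))
            ti, vi = ids.get_indexer(train), ids.get_indexer(val)
            yv = y_focal.reindex(val).to_numpy()
            Ktt = Kv[np.ix_(ti, ti)]
            r = reml_kernel(y_focal.reindex(train).to_numpy(), Ktt)
            alpha = linalg.solve(Ktt + r.delta * np.eye(len(train)), r.resid,
                                 assume_a="pos")
            uni.append(prediction_accuracy(Kv[np.ix_(vi, ti)] @ alpha, yv))

            rp = reml_kernel(y_proxy.reindex(train).to_numpy(), Ktt)
            ap = linalg.solve(Ktt + rp.delta * np.eye(len(train)), rp.resid,
                              assume_a="pos")
            proxy_gebv = pd.Series(Kv[:, ti] @ ap, index=ids)
            pred = model_based_index(y_focal.reindex(train), proxy_gebv, A,
                                     train)
            idx.append(prediction_accuracy(pred.iloc[vi], yv))

            # 90% of the focal training records masked
            n_keep = len(train) - int(round(0.9 * len(train)))
            kept = pd.Index(rng.choice(train, size=n_keep, replace=False))
            ki = ids.get_indexer(kept)
            Kkk = Kv[np.ix_(ki, ki)]
            try:
                rk = reml_kernel(y_focal.reindex(kept).to_numpy(), Kkk)
                ak = linalg.solve(Kkk + rk.delta * np.eye(len(kept)),
                                  rk.resid, assume_a="pos")
                uni90.append(prediction_accuracy(
                    Kv[np.ix_(vi, ki)] @ ak, yv))
            except Exception:
                uni90.append(np.nan)
            biv = predict_with_pheno_proxy(y_focal.reindex(kept), y_proxy,
                                           A, kept)
            biv90.append(prediction_accuracy(biv.iloc[vi], yv))
    return {
        "univariate": float(np.nanmean(uni)),
        "model_based_index": float(np.nanmean(idx)),
        "univariate_90pct_missing": float(np.nanmean(uni90)),
        "bivariate_90pct_missing": float(np.nanmean(biv90)),
    }
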
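"""Shared fixtures: desk-scale simulated populations with known truth."""

import numpy as np
import pytest

import orchardgs as og


@pytest.fixture(scope="session")
def desk_population():
    """153 F1 progeny x 640 SNPs, one oligogenic trait (h2 = 0.7)."""
    design = og.CrossDesign(seed=1)
    arch = og.TraitArchitecture(traits=("T",), h2_target=0.7, n_qtl=30)
    geno, pheno, truth = og.simulate_population(design, arch)
    return geno, pheno, truth


@pytest.fixture(scope="session")
def adjusted_desk(desk_population):
    geno, pheno, truth = desk_population
    adjusted, results = og.adjust_all_traits(pheno)
    return geno, adjusted, truth, results


@pytest.fixture(scope="session")
def desk_grm(desk_population):
    geno, _, _ = desk_population
    return og.compute_grm(geno)


def genotype_means(pheno, trait):
    """Raw genotype-level means: a cheap stand-in for adjusted values when a
    test does not need the mixed model itself."""
    sub = pheno[pheno["trait"] == trait]
    return sub.groupby("genotype")["value"].mean()


@pytest.fixture(scope="session")
def bivariate_population():
    """Correlated trait pair (r_g = 0.8) for multi-trait tests."""
    design = og.CrossDesign(seed=21)
    arch = og.TraitArchitecture(
        traits=("focal", "proxy"), h2_target=(0.45, 0.9), n_qtl=40,
        genetic_corr=np.array([[1.0, 0.8], [0.8, 1.0]]))
    geno, pheno, truth = og.simulate_population(design, arch)
    y1 = genotype_means(pheno, "focal")
    y2 = genotype_means(pheno, "proxy")
    A = og.compute_grm(geno)
    return geno, y1, y2, A, truth
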
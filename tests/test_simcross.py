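"""Cross simulator: segregation classes, meiosis, phenotype generation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import orchardgs as og
from orchardgs.simcross import (Parents, haldane_r, kosambi_r, kosambi_cM,
                                simulate_parents, simulate_progeny,
                                simulate_phenotypes)


def _manual_parents(positions, seg_class="abxaa", chrom=1):
    """Parents with hand-placed markers (parent het per class)."""
    m = len(positions)
    marker_map = pd.DataFrame({
        "marker": [f"m{i}" for i in range(m)],
        "chrom": chrom, "pos_cM": positions, "seg_class": seg_class})
    hap = np.zeros((2, 2, m), dtype=np.int8)
    if seg_class in ("abxaa", "abxab"):
        hap[0, 0] = 1
    if seg_class in ("aaxab", "abxab"):
        hap[1, 0] = 1
    return Parents(haplotypes=hap, marker_map=marker_map)


class TestSimulateParents:
    def test_degenerate_class_mix_makes_parent2_homozygous(self):
        design = og.CrossDesign(seg_class_probs=(1.0, 0.0, 0.0), seed=0,
                                n_chrom=2, markers_per_chrom=50)
        parents = simulate_parents(design)
        assert np.all(parents.haplotypes[1, 0] == parents.haplotypes[1, 1])
        # parent 1 heterozygous at every marker in this mix
        assert np.all(parents.haplotypes[0, 0] != parents.haplotypes[0, 1])

    def test_class_counts_match_multinomial_expectation(self):
        probs = (0.45, 0.35, 0.20)
        design = og.CrossDesign(seg_class_probs=probs, seed=3,
                                n_chrom=8, markers_per_chrom=125)
        parents = simulate_parents(design)
        counts = parents.marker_map["seg_class"].value_counts()
        n = 1000
        for cls, p in zip(("abxaa", "aaxab", "abxab"), probs):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[cls] - n * p) < 3 * sd

    def test_seed_reproducibility(self):
        d = og.CrossDesign(seed=11)
        p1, p2 = simulate_parents(d), simulate_parents(d)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        pd.testing.assert_frame_equal(p1.marker_map, p2.marker_map)

    def test_positions_sorted_within_chromosome(self):
        parents = simulate_parents(og.CrossDesign(seed=5))
        for _, grp in parents.marker_map.groupby("chrom"):
            assert grp["pos_cM"].is_monotonic_increasing

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            og.CrossDesign(markers_per_chrom=0)
        with pytest.raises(ValueError):
            og.CrossDesign(seg_class_probs=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            og.CrossDesign(chrom_length_cM=-10.0)


class TestSimulateProgeny:
    def test_complete_linkage_markers_identical(self):
        parents = _manual_parents([20.0, 20.0], "abxaa")
        design = og.CrossDesign(n_progeny=100, n_chrom=1,
                                chrom_length_cM=(50.0,), markers_per_chrom=2,
                                seed=2)
        geno, _ = simulate_progeny(parents, design,
                                   np.random.default_rng(2))
        d = geno.dosage.to_numpy()
        assert np.array_equal(d[:, 0], d[:, 1])

    def test_testcross_marker_segregates_1_to_1(self):
        # many abxaa markers across chromosomes; chi-square 1:1 should pass
        # at alpha = 0.01 for >= 95% of them
        design = og.CrossDesign(n_progeny=500, n_chrom=8,
                                markers_per_chrom=25,
                                seg_class_probs=(1.0, 0.0, 0.0), seed=7)
        parents = simulate_parents(design)
        geno, _ = simulate_progeny(parents, design, np.random.default_rng(8))
        d = geno.dosage.to_numpy()
        pvals = [stats.chisquare([np.sum(c == 0), np.sum(c == 1)]).pvalue
                 for c in d.T]
        assert np.mean(np.asarray(pvals) > 0.01) >= 0.95

    def test_intercross_marker_segregates_1_2_1(self):
        design = og.CrossDesign(n_progeny=500, n_chrom=8,
                                markers_per_chrom=25,
                                seg_class_probs=(0.0, 0.0, 1.0), seed=9)
        parents = simulate_parents(design)
        geno, _ = simulate_progeny(parents, design, np.random.default_rng(10))
        d = geno.dosage.to_numpy()
        pvals = [stats.chisquare(
            [np.sum(c == 0), np.sum(c == 1), np.sum(c == 2)],
            [len(c) / 4, len(c) / 2, len(c) / 4]).pvalue for c in d.T]
        assert np.mean(np.asarray(pvals) > 0.01) >= 0.95

    def test_recombination_fraction_matches_map_function(self):
        # two markers 50 cM apart; meiosis is Poisson/no-interference, so the
        # expected recombination fraction is Haldane's
        parents = _manual_parents([0.0, 50.0], "abxaa")
        design = og.CrossDesign(n_progeny=2000, n_chrom=1,
                                chrom_length_cM=(50.0,), markers_per_chrom=2,
                                seed=3)
        geno, truth = simulate_progeny(parents, design,
                                       np.random.default_rng(4))
        g1 = truth.progeny_haplotypes[:, 0, :]  # gametes from the het parent
        r_emp = np.mean(g1[:, 0] != g1[:, 1])
        assert abs(r_emp - haldane_r(50.0)) < 0.03

    def test_dosages_in_valid_range(self, desk_population):
        geno, _, _ = desk_population
        assert set(np.unique(geno.dosage.to_numpy())) <= {0.0, 1.0, 2.0}

    def test_grm_within_family_centering(self):
        # within a single full-sib family every progeny is an independent
        # draw of parental gametes, so the founder-frequency-scaled GRM has
        # mean off-diagonal near zero (pairwise IBD sharing shows up as
        # spread around it, not as a 0.5 offset)
        design = og.CrossDesign(n_progeny=200, seed=13)
        parents = simulate_parents(design)
        geno, _ = simulate_progeny(parents, design, np.random.default_rng(14))
        founder_p = parents.haplotypes.reshape(4, -1).mean(axis=0)
        poly = (founder_p > 0) & (founder_p < 1)
        sub = geno._subset_markers(poly)
        grm = og.compute_grm(sub, allele_freq=founder_p[poly])
        A = grm.values
        off = A[~np.eye(len(A), dtype=bool)]
        assert abs(off.mean()) < 0.1
        assert off.std() > 0.05  # IBD variation across sib pairs


class TestKosambi:
    def test_round_trip(self):
        for d in (1.0, 10.0, 50.0, 100.0):
            assert kosambi_cM(kosambi_r(d)) == pytest.approx(d, rel=1e-9)

    def test_small_distance_limit(self):
        assert kosambi_r(1.0) == pytest.approx(0.01, rel=0.01)


class TestSimulatePhenotypes:
    def test_noise_free_limit_replicates_identical_up_to_lot_shifts(self):
        arch = og.TraitArchitecture(traits=("A",), h2_target=1.0,
                                    var_year=0.0, lot_shifts=(-1.0, 0.0, 1.0))
        design = og.CrossDesign(seed=17, n_progeny=30, n_chrom=2,
                                markers_per_chrom=40)
        geno, pheno, truth = og.simulate_population(design, arch)
        wide = pheno.pivot_table(index="genotype", columns=["year", "lot"],
                                 values="value")
        centered = wide - np.array([c[1] - 2.0 for c in wide.columns]) * 1.0
        # after removing lot shifts every replicate equals the TBV + mu
        assert np.allclose(centered.std(axis=1), 0.0, atol=1e-9)

    def test_regression_of_genotype_means_on_tbv_near_unity(self):
        slopes = []
        for seed in range(20):
            design = og.CrossDesign(seed=100 + seed, n_progeny=300,
                                    n_chrom=4, markers_per_chrom=40)
            arch = og.TraitArchitecture(traits=("A",), h2_target=0.6)
            geno, pheno, truth = og.simulate_population(design, arch)
            gm = pheno.groupby("genotype")["value"].mean()
            tbv = truth.true_breeding_values["A"].reindex(gm.index)
            slopes.append(np.polyfit(tbv, gm, 1)[0])
        assert 0.8 < np.mean(slopes) < 1.2

    def test_genetic_correlation_flows_into_tbv(self):
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        arch = og.TraitArchitecture(traits=("A", "B"), genetic_corr=corr,
                                    h2_target=0.6, n_qtl=60)
        design = og.CrossDesign(seed=23, n_progeny=300, n_chrom=4,
                                markers_per_chrom=40)
        _, _, truth = og.simulate_population(design, arch)
        r = truth.true_breeding_values.corr().iloc[0, 1]
        assert 0.8 <= r <= 0.97

    def test_realized_heritability_tracks_target(self):
        for target in (0.3, 0.8):
            h2s = []
            for seed in range(10):
                design = og.CrossDesign(seed=400 + seed, n_progeny=300,
                                        n_chrom=4, markers_per_chrom=40)
                arch = og.TraitArchitecture(traits=("A",), h2_target=target)
                _, pheno, truth = og.simulate_population(design, arch)
                gm = pheno.groupby("genotype")["value"].mean()
                tbv = truth.true_breeding_values["A"].reindex(gm.index)
                h2s.append(tbv.var() / gm.var())
            assert abs(np.mean(h2s) - target) < 0.1

    def test_non_psd_genetic_corr_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            og.TraitArchitecture(traits=("A", "B"), genetic_corr=bad)

    def test_tbv_equals_qtl_dosage_times_effects(self, desk_population):
        geno, _, truth = desk_population
        Q = geno.dosage.to_numpy()[:, truth.qtl_indices]
        tbv = Q @ truth.qtl_effects
        tbv -= tbv.mean(axis=0)
        assert np.allclose(tbv, truth.true_breeding_values.to_numpy(),
                           atol=1e-9)


class TestWriters:
    def test_vcf_round_trip(self, tmp_path, desk_population):
        geno, _, _ = desk_population
        path = tmp_path / "pop.vcf"
        og.simcross.write_vcf(geno, path)
        back = og.read_genotypes(path, "vcf")
        assert np.allclose(back.dosage.to_numpy(), geno.dosage.to_numpy())
        assert list(back.dosage.index) == list(geno.dosage.index)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = tmp_path / "cross.yaml"
        cfg.write_text(
            "design:\n  n_progeny: 60\n  n_chrom: 2\n"
            "  markers_per_chrom: 30\n  seed: 5\n"
            "architecture:\n  traits: [A, B]\n  h2_target: [0.5, 0.8]\n"
            "  genetic_corr: [[1.0, 0.6], [0.6, 1.0]]\n")
        design, arch = og.simcross.design_from_yaml(cfg)
        assert design.n_progeny == 60
        assert arch.h2_target == (0.5, 0.8)
        geno, pheno, truth = og.simulate_population(design, arch)
        assert geno.dosage.shape == (60, 60)
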
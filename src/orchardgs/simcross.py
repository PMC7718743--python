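"""Synthetic F1 pseudo-testcross populations with known genetic truth.

Emulates a biparental cross of two highly heterozygous outbred parents
(the situation of stone-fruit mapping populations): every marker belongs
to a pseudo-testcross segregation class —

* ``ab x aa`` — heterozygous in parent 1 only, segregates 1:1;
* ``aa x ab`` — heterozygous in parent 2 only, segregates 1:1;
* ``ab x ab`` — heterozygous in both parents, segregates 1:2:1.

Meiosis draws crossover counts Poisson(L/100) per chromosome with uniform
placement (no interference); Kosambi's map function is used only when
converting map distance to an expected recombination fraction for
validation.  Multi-trait phenotypes follow the same generative structure
the adjustment model assumes: genotype value + year + maturity-lot shift +
genotype-by-year interaction + residual, with the residual scale chosen so
the genotype-mean-level heritability matches its target in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CrossDesign", "TraitArchitecture", "Parents", "TruthSet",
    "simulate_parents", "simulate_progeny", "simulate_phenotypes",
    "simulate_population", "kosambi_r", "kosambi_cM",
    "write_vcf", "write_dosage_csv", "write_phenotype_csv", "write_truth_json",
    "design_from_yaml", "apricot_like_architecture",
]

SEG_CLASSES = ("abxaa", "aaxab", "abxab")


def kosambi_r(d_cM: float) -> float:
    """Recombination fraction for a map distance under Kosambi's function."""
    x = np.asarray(d_cM, dtype=float) / 50.0
    return 0.5 * np.tanh(x)


def kosambi_cM(r: float) -> float:
    """Inverse Kosambi: map distance (cM) for a recombination fraction."""
    r = np.asarray(r, dtype=float)
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def haldane_r(d_cM: float) -> float:
    """Recombination fraction under Haldane (no interference), the model
    implied by Poisson crossovers with uniform placement."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass
class CrossDesign:
    """Layout of a simulated biparental cross.

    Defaults mirror the desk-scale stand-in for the study population:
    153 progeny, 8 chromosomes of 90 cM carrying 80 markers each (640 SNPs),
    with a segregation-class mix of 45/35/20% (the real mix is unreported;
    this is a free parameter).
    """

    n_progeny: int = 153
    n_chrom: int = 8
    chrom_length_cM: tuple[float, ...] | float = 90.0
    markers_per_chrom: int = 80
    seg_class_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)
    seed: int | None = None

    def __post_init__(self):
        if np.isscalar(self.chrom_length_cM):
            self.chrom_length_cM = tuple(
                float(self.chrom_length_cM) for _ in range(self.n_chrom))
        if self.n_progeny < 1 or self.n_chrom < 1 or self.markers_per_chrom < 1:
            raise ValueError("counts must be >= 1")
        if len(self.chrom_length_cM) != self.n_chrom:
            raise ValueError("need one map length per chromosome")
        if any(L <= 0 for L in self.chrom_length_cM):
            raise ValueError("map lengths must be positive")
        p = np.asarray(self.seg_class_probs, dtype=float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("seg_class_probs must be 3 non-negative values summing to 1")

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom


@dataclass
class TraitArchitecture:
    """Genetic architectures of the simulated traits.

    ``n_qtl`` loci are shared across traits; per-locus effect vectors are
    drawn from a multivariate normal with correlation ``genetic_corr`` so
    that breeding values are genetically correlated through pleiotropy.
    ``major_qtl_share[t]`` routes that fraction of trait t's genetic
    variance through one designated locus (0 = fully polygenic).
    ``var_year`` is the year-main-effect variance relative to the genetic
    variance of each trait.  ``var_gxy`` is the share of the *non-genetic
    genotype-level variance* (fixed by ``h2_target``) carried by the
    genotype-by-year interaction, the rest going to the residual — so any
    heritability target in (0, 1] is internally consistent.  ``lot_shifts``
    are fixed maturity-lot offsets in units of the (unit-genetic-variance)
    simulated scale.
    """

    traits: tuple[str, ...] = ("T1",)
    n_qtl: int = 20
    qtl_effect_sd: float = 1.0
    h2_target: tuple[float, ...] | float = 0.6
    major_qtl_share: tuple[float, ...] | float = 0.0
    genetic_corr: np.ndarray | None = None
    var_year: float = 0.15
    var_gxy: float = 0.25
    lot_shifts: tuple[float, ...] = (-0.5, 0.0, 0.5)

    def __post_init__(self):
        t = len(self.traits)
        if np.isscalar(self.h2_target):
            self.h2_target = (float(self.h2_target),) * t
        if np.isscalar(self.major_qtl_share):
            self.major_qtl_share = (float(self.major_qtl_share),) * t
        if self.genetic_corr is None:
            self.genetic_corr = np.eye(t)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        if self.genetic_corr.shape != (t, t):
            raise ValueError("genetic_corr must be traits x traits")
        if not np.allclose(self.genetic_corr, self.genetic_corr.T):
            raise ValueError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(self.genetic_corr), 1.0):
            raise ValueError("genetic_corr must have unit diagonal")
        w = np.linalg.eigvalsh(self.genetic_corr)
        if w.min() < -1e-8:
            raise ValueError("genetic_corr is not positive semi-definite")
        if any(not (0 < h <= 1) for h in self.h2_target):
            raise ValueError("h2_target must lie in (0, 1]")
        if any(not (0 <= s <= 1) for s in self.major_qtl_share):
            raise ValueError("major_qtl_share must lie in [0, 1]")


def apricot_like_architecture(n_traits: int = 4) -> TraitArchitecture:
    """Architecture emulating fruit-quality traits: a mix of oligogenic
    traits carrying a major QTL and polygenic traits, moderate-to-high
    heritabilities, one strongly correlated trait pair."""
    names = tuple(f"T{i + 1}" for i in range(n_traits))
    corr = np.eye(n_traits)
    if n_traits >= 2:
        corr[0, 1] = corr[1, 0] = 0.8
    h2 = tuple(np.linspace(0.9, 0.55, n_traits))
    share = tuple(0.5 if i % 2 == 0 else 0.0 for i in range(n_traits))
    return TraitArchitecture(traits=names, n_qtl=20, h2_target=h2,
                             major_qtl_share=share, genetic_corr=corr)


@dataclass
class Parents:
    """Phased parental haplotypes plus the marker map."""

    haplotypes: np.ndarray  # (2 parents, 2 haplotypes, n_markers) in {0,1}
    marker_map: pd.DataFrame  # marker, chrom, pos_cM, seg_class


@dataclass
class TruthSet:
    """Ground truth of a simulated population, for parameter-recovery tests."""

    parental_haplotypes: np.ndarray
    progeny_haplotypes: np.ndarray  # (n_progeny, 2, n_markers)
    marker_map: pd.DataFrame
    qtl_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    qtl_effects: np.ndarray | None = None  # (n_qtl, n_traits)
    true_breeding_values: pd.DataFrame | None = None

    @property
    def qtl_positions(self) -> pd.DataFrame:
        return self.marker_map.iloc[self.qtl_indices][["marker", "chrom", "pos_cM"]]


def _child_rngs(seed, n):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def simulate_parents(design: CrossDesign, rng: np.random.Generator | None = None) -> Parents:
    """Draw the parental haplotypes and the marker map for a cross design.

    Parent 1 is heterozygous exactly at ``abxaa`` and ``abxab`` markers,
    parent 2 at ``aaxab`` and ``abxab`` markers; homozygous parents carry
    the reference allele.  Heterozygote phase is random.
    """
    if rng is None:
        rng = _child_rngs(design.seed, 3)[0]
    m = design.n_markers
    classes = rng.choice(3, size=m, p=np.asarray(design.seg_class_probs))
    chrom = np.repeat(np.arange(1, design.n_chrom + 1), design.markers_per_chrom)
    pos = np.concatenate([
        np.sort(rng.uniform(0, design.chrom_length_cM[c], design.markers_per_chrom))
        for c in range(design.n_chrom)])
    marker_map = pd.DataFrame({
        "marker": [f"chr{c}_m{i}" for i, c in enumerate(chrom)],
        "chrom": chrom, "pos_cM": pos,
        "seg_class": [SEG_CLASSES[k] for k in classes]})

    hap = np.zeros((2, 2, m), dtype=np.int8)
    het1 = (classes == 0) | (classes == 2)
    het2 = (classes == 1) | (classes == 2)
    for p, het in enumerate((het1, het2)):
        phase = rng.integers(0, 2, size=m)
        hap[p, 0, het] = phase[het]
        hap[p, 1, het] = 1 - phase[het]
    return Parents(haplotypes=hap, marker_map=marker_map)


def _gametes(parent_hap: np.ndarray, marker_map: pd.DataFrame, n: int,
             rng: np.random.Generator) -> np.ndarray:
    """Draw n recombinant gametes from one parent (Poisson crossovers)."""
    m = parent_hap.shape[1]
    out = np.empty((n, m), dtype=np.int8)
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos_cM"].to_numpy()
        L = pos.max() if len(pos) else 0.0
        # full chromosome extent: use map length implied by outermost markers
        for i in range(n):
            k = rng.poisson(L / 100.0)
            xo = np.sort(rng.uniform(0.0, L, size=k)) if k else np.empty(0)
            start = rng.integers(0, 2)
            # phase at a marker flips once per crossover to its left
            phase = (start + np.searchsorted(xo, pos)) % 2
            out[i, idx] = parent_hap[phase, idx]
    return out


def simulate_progeny(parents: Parents, design: CrossDesign,
                     rng: np.random.Generator | None = None):
    """Simulate the F1 progeny; returns (dosage GenotypeMatrix, TruthSet).

    Each progeny genome is one recombinant gamete per parent; dosage is the
    count of alternative-allele copies (0/1/2).
    """
    from .genotypes import GenotypeMatrix

    if rng is None:
        rng = _child_rngs(design.seed, 3)[1]
    n = design.n_progeny
    g1 = _gametes(parents.haplotypes[0], parents.marker_map, n, rng)
    g2 = _gametes(parents.haplotypes[1], parents.marker_map, n, rng)
    dosage = (g1 + g2).astype(float)
    ids = [f"F1_{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=ids,
                            columns=parents.marker_map["marker"].to_numpy()),
        markers=parents.marker_map.set_index("marker").assign(
            pos=lambda d: (d["pos_cM"] * 1e6 / 2).round().astype(int) + 1))
    truth = TruthSet(parental_haplotypes=parents.haplotypes,
                     progeny_haplotypes=np.stack([g1, g2], axis=1),
                     marker_map=parents.marker_map)
    return gm, truth


def simulate_phenotypes(geno, truth: TruthSet, arch: TraitArchitecture,
                        n_years: int = 2, n_lots: int = 3,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Attach QTL effects and draw multi-year, multi-lot phenotypes.

    The phenotypic model per record is
    ``y = mu + TBV + year + lot_shift + gxy + e`` with the residual variance
    solved from the genotype-mean-level heritability target:
    ``h2 = Vg / (Vg + var_gxy/ny + var_e/(ny*nl))`` (year main effects are
    shared by all genotypes and cancel from genotype-level variance).
    Fills ``truth.qtl_effects`` / ``truth.true_breeding_values`` in place
    and returns a long-format phenotype table.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    nt = len(arch.traits)
    if len(arch.lot_shifts) < n_lots:
        raise ValueError("need one lot shift per lot")
    dosage = geno.dosage.to_numpy()
    n_ind, m = dosage.shape
    if arch.n_qtl > m:
        raise ValueError("more QTL requested than simulated loci")

    qtl_idx = np.sort(rng.choice(m, size=arch.n_qtl, replace=False))
    # pleiotropic effects: correlated across traits per genetic_corr
    Lc = np.linalg.cholesky(arch.genetic_corr + 1e-10 * np.eye(nt))
    eff = rng.standard_normal((arch.n_qtl, nt)) @ Lc.T * arch.qtl_effect_sd

    Q = dosage[:, qtl_idx]
    for t, share in enumerate(arch.major_qtl_share):
        if share <= 0 or arch.n_qtl < 2:
            continue
        # rescale the designated (first) locus so it carries `share` of Vg
        v_major = np.var(Q[:, 0] * eff[0, t])
        v_rest = np.var(Q[:, 1:] @ eff[1:, t])
        if v_major > 0 and v_rest > 0:
            eff[0, t] *= np.sqrt(share / (1 - share) * v_rest / v_major)

    tbv = Q @ eff
    tbv -= tbv.mean(axis=0)
    # enforce the target genetic covariance exactly on the realized TBVs:
    # LD between linked loci leaves few independent segments in a biparental
    # cross, so without this the realized trait correlation drifts far from
    # genetic_corr.  Recombining the per-locus effect vectors keeps the
    # truth invariant TBV = Q @ eff intact.
    if nt == 1:
        sd = tbv.std(axis=0)
        sd[sd == 0] = 1.0
        tbv /= sd
        eff /= sd
    else:
        cov = np.cov(tbv, rowvar=False)
        Lw = np.linalg.cholesky(cov + 1e-10 * np.eye(nt))
        mix = np.linalg.solve(Lw, np.eye(nt)).T @ Lc.T
        tbv = tbv @ mix
        eff = eff @ mix

    truth.qtl_indices = qtl_idx
    truth.qtl_effects = eff
    truth.true_breeding_values = pd.DataFrame(
        tbv, index=geno.dosage.index, columns=list(arch.traits))

    records = []
    years = [2006 + j for j in range(n_years)]
    for t, trait in enumerate(arch.traits):
        vg = float(np.var(tbv[:, t]))
        h2 = arch.h2_target[t]
        s_y2 = arch.var_year * vg
        # total genotype-mean-level nuisance fixed by the h2 target, split
        # between G x Y and residual per var_gxy
        nuisance = vg * (1.0 / h2 - 1.0)
        s_gy2 = n_years * arch.var_gxy * nuisance
        s_e2 = n_years * n_lots * (1.0 - arch.var_gxy) * nuisance
        year_eff = rng.normal(0, np.sqrt(s_y2), n_years)
        gxy = rng.normal(0, np.sqrt(s_gy2), (n_ind, n_years))
        e = rng.normal(0, np.sqrt(s_e2), (n_ind, n_years, n_lots))
        for i, gid in enumerate(geno.dosage.index):
            for j in range(n_years):
                for k in range(n_lots):
                    records.append((gid, years[j], k + 1, trait,
                                    tbv[i, t] + year_eff[j]
                                    + arch.lot_shifts[k] + gxy[i, j]
                                    + e[i, j, k]))
    return pd.DataFrame(records,
                        columns=["genotype", "year", "lot", "trait", "value"])


def simulate_population(design: CrossDesign, arch: TraitArchitecture,
                        n_years: int = 2, n_lots: int = 3):
    """One-call pipeline: parents -> progeny -> phenotypes.

    The design's global seed fans out to independent per-stage child seeds,
    so each stage is reproducible on its own.
    Returns (GenotypeMatrix, PhenotypeTable, TruthSet).
    """
    r_par, r_prog, r_phen = _child_rngs(design.seed, 3)
    parents = simulate_parents(design, r_par)
    geno, truth = simulate_progeny(parents, design, r_prog)
    pheno = simulate_phenotypes(geno, truth, arch, n_years, n_lots, r_phen)
    return geno, pheno, truth


# ---------------------------------------------------------------- writers

def write_vcf(geno, path) -> None:
    """Write a dosage matrix as a minimal VCF 4.2 (GT only, one contig per
    chromosome). Missing dosages become ./. ; fractional (imputed) dosages
    are not representable and raise."""
    d = geno.dosage
    vals = d.to_numpy()
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ValueError("VCF output requires integer dosages 0/1/2 or missing")
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(d.index) + "\n")
        for j, mk in enumerate(d.columns):
            meta = geno.markers.loc[mk]
            pos = int(meta["pos"]) if "pos" in meta else j + 1
            calls = "\t".join("./." if np.isnan(v) else gt[v] for v in vals[:, j])
            fh.write(f"{meta['chrom']}\t{pos}\t{mk}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def write_dosage_csv(geno, path) -> None:
    geno.dosage.to_csv(path, index_label="id")


def write_phenotype_csv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def write_truth_json(truth: TruthSet, path) -> None:
    payload = {
        "qtl": truth.qtl_positions.to_dict(orient="records"),
        "qtl_effects": None if truth.qtl_effects is None
        else truth.qtl_effects.tolist(),
        "true_breeding_values": None if truth.true_breeding_values is None
        else truth.true_breeding_values.round(6).to_dict(orient="index"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def design_from_yaml(path) -> tuple[CrossDesign, TraitArchitecture]:
    """Load a CrossDesign + TraitArchitecture from a YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    d = cfg.get("design", {})
    a = cfg.get("architecture", {})
    if "genetic_corr" in a:
        a["genetic_corr"] = np.asarray(a["genetic_corr"], dtype=float)
    for key in ("traits", "lot_shifts", "h2_target", "major_qtl_share"):
        if key in a and isinstance(a[key], list):
            a[key] = tuple(a[key])
    if "chrom_length_cM" in d and isinstance(d["chrom_length_cM"], list):
        d["chrom_length_cM"] = tuple(d["chrom_length_cM"])
    return CrossDesign(**d), TraitArchitecture(**a)
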
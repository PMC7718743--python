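"""Genotype containers, QC filters, imputation and the genomic relationship
matrix (GRM).

Dosages are counts of the alternative allele (0/1/2; NaN while missing,
real-valued in [0, 2] after mean imputation).  Marker segregation is tested
against the pseudo-testcross expectation of the marker's class (1:1 for
single-heterozygous-parent markers, 1:2:1 for double-heterozygous ones);
the class is inferred from the observed genotype classes unless parental
genotypes are supplied.  The GRM follows VanRaden:
``A = WW' / (2 * sum_i p_i (1 - p_i))`` with ``W`` the dosage matrix coded
about heterozygotes ({-1, 0, 1}) and, by default, additionally centered by
the empirical allele frequencies (``W = dosage - 2p``); the plain
{-1, 0, 1} coding is available as the uncentered variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "GRM", "read_genotypes", "filter_markers",
           "impute_mean", "segregation_filter", "segregation_test_pvalues",
           "compute_grm", "subsample_markers"]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage table with marker metadata.

    ``dosage``: DataFrame, rows = individuals, columns = marker ids,
    values in {0, 1, 2} or NaN (real-valued after imputation).
    ``markers``: DataFrame indexed by marker id with at least ``chrom`` and
    ``pos`` (bp); optional ``pos_cM``, ``seg_class``, ``gq``.
    """

    dosage: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self):
        if not self.dosage.columns.equals(self.markers.index):
            self.markers = self.markers.loc[self.dosage.columns]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def individuals(self) -> pd.Index:
        return self.dosage.index

    def missing_rate(self) -> pd.Series:
        return self.dosage.isna().mean(axis=0)

    def drop_individuals(self, exclude) -> "GenotypeMatrix":
        """Remove listed individuals (e.g. known spurious profiles)."""
        keep = ~self.dosage.index.isin(list(exclude))
        return GenotypeMatrix(self.dosage.loc[keep], self.markers.copy())

    def _subset_markers(self, keep_mask) -> "GenotypeMatrix":
        cols = self.dosage.columns[keep_mask]
        return GenotypeMatrix(self.dosage[cols], self.markers.loc[cols])

    def position_column(self) -> str:
        return "pos_cM" if "pos_cM" in self.markers.columns else "pos"


@dataclass
class GRM:
    """VanRaden genomic relationship matrix."""

    A: pd.DataFrame
    denominator: float
    allele_freq: pd.Series
    ridge: float = 1e-6

    @property
    def values(self) -> np.ndarray:
        return self.A.to_numpy()

    def to_tsv(self, path) -> None:
        self.A.to_csv(path, sep="\t", index_label="id")


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT and, when present, GQ) or a dosage CSV.

    VCF: GT fields become alternative-allele dosages; ``./.`` stays missing;
    multi-allelic records are skipped (count logged); per-marker ``gq`` is
    the mean genotype quality over called individuals.
    CSV: individuals as rows (first column = id), header = marker ids;
    marker metadata defaults to a single pseudo-chromosome.
    """
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        markers = pd.DataFrame({"chrom": 0, "pos": np.arange(1, df.shape[1] + 1)},
                               index=df.columns)
        return GenotypeMatrix(df.astype(float), markers)
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta, skipped = [], [], 0
    code = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}  # cyvcf2 gt_types
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            skipped += 1
            continue
        try:
            dos = np.array([code[t] for t in var.gt_types])
        except KeyError as err:
            raise ValueError(f"malformed record #{i + 1} at "
                             f"{var.CHROM}:{var.POS}") from err
        rows.append(dos)
        quals = var.gt_quals
        gq = (float(np.nanmean(quals[quals >= 0]))
              if quals is not None and np.any(quals >= 0) else np.nan)
        meta.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, gq))
    if skipped:
        logger.info("skipped %d multi-allelic records", skipped)
    if not rows:
        raise ValueError("no biallelic records found")
    markers = pd.DataFrame(meta, columns=["marker", "chrom", "pos", "gq"]) \
        .set_index("marker")
    dosage = pd.DataFrame(np.column_stack(rows), index=samples,
                          columns=markers.index)
    return GenotypeMatrix(dosage, markers)


def filter_markers(geno: GenotypeMatrix, min_gq: float = 20.0,
                   max_missing: float = 0.05) -> GenotypeMatrix:
    """Drop markers with genotype quality <= min_gq or missingness >= max_missing.

    Markers without a quality score pass the quality criterion.
    """
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must be in [0, 1]")
    miss = geno.missing_rate().to_numpy()
    keep = miss < max_missing if max_missing < 1 else np.ones_like(miss, bool)
    if "gq" in geno.markers.columns and min_gq > 0:
        gq = geno.markers["gq"].to_numpy(dtype=float)
        keep &= np.isnan(gq) | (gq > min_gq)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all markers removed; review GQ/missingness thresholds")
    logger.info("filter_markers removed %d of %d markers", n_removed, keep.size)
    return geno._subset_markers(keep)


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-marker mean of observed dosages."""
    if geno.dosage.isna().all(axis=0).any():
        bad = geno.dosage.columns[geno.dosage.isna().all(axis=0)][0]
        raise ValueError(f"marker {bad!r} has no observed calls; filter first")
    return GenotypeMatrix(geno.dosage.fillna(geno.dosage.mean(axis=0)),
                          geno.markers.copy())


def _expected_ratio(obs_counts: np.ndarray, seg_class: str | None):
    """Expected class proportions for a marker given (or inferred from) its
    segregation class.  Two observed genotype classes imply a 1:1 testcross
    marker; three imply 1:2:1."""
    present = np.flatnonzero(obs_counts)
    if seg_class in ("abxaa", "aaxab"):
        if present.size < 2:
            return None, None
        classes = present if present.size == 2 \
            else np.sort(np.argsort(obs_counts)[-2:])
        return np.array([0.5, 0.5]), classes
    if seg_class == "abxab":
        return np.array([0.25, 0.5, 0.25]), np.array([0, 1, 2])
    if present.size <= 1:
        return None, None  # monomorphic: nothing to test
    if present.size == 2:
        return np.array([0.5, 0.5]), present
    return np.array([0.25, 0.5, 0.25]), np.array([0, 1, 2])


def segregation_test_pvalues(geno: GenotypeMatrix) -> pd.Series:
    """Chi-square goodness-of-fit p-value of each marker against its
    pseudo-testcross segregation ratio (monomorphic markers get p = NaN).
    Falls back to an exact binomial test when an expected count is < 1."""
    pvals = np.full(geno.n_markers, np.nan)
    seg = geno.markers.get("seg_class")
    vals = geno.dosage.to_numpy()
    for j in range(geno.n_markers):
        col = vals[:, j]
        col = col[~np.isnan(col)]
        counts = np.array([(col == c).sum() for c in (0, 1, 2)])
        sc = None if seg is None else seg.iloc[j]
        probs, classes = _expected_ratio(counts, sc)
        if probs is None:
            continue
        obs = counts[classes]
        exp = probs * obs.sum()
        if obs.sum() == 0:
            continue
        if exp.min() < 1 and len(obs) == 2:
            pvals[j] = stats.binomtest(int(obs[0]), int(obs.sum()), 0.5).pvalue
        else:
            pvals[j] = stats.chisquare(obs, exp).pvalue
    return pd.Series(pvals, index=geno.dosage.columns)


def segregation_filter(geno: GenotypeMatrix,
                       p_threshold: float = 1e-6) -> GenotypeMatrix:
    """Remove markers whose segregation deviates from the Mendelian
    pseudo-testcross expectation at p < threshold (default 1e-6)."""
    p = segregation_test_pvalues(geno)
    keep = ~(p < p_threshold)  # NaN (monomorphic) markers are retained
    logger.info("segregation_filter removed %d of %d markers",
                int((~keep).sum()), keep.size)
    return geno._subset_markers(keep.to_numpy())


def compute_grm(geno: GenotypeMatrix, centered: bool = True,
                ridge: float = 1e-6, allele_freq=None) -> GRM:
    """VanRaden GRM from an imputed dosage matrix.

    ``centered=True`` (default) centers each marker by twice its empirical
    allele frequency; ``centered=False`` uses the plain {-1, 0, 1} coding
    (its special case at p = 0.5).  ``allele_freq`` overrides the empirical
    frequencies (e.g. founder frequencies, under which full sibs show the
    pedigree expectation of 0.5).  A small ridge on the diagonal keeps the
    matrix invertible for BLUP solvers.
    """
    M = geno.dosage.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("impute before computing the GRM")
    if allele_freq is not None:
        p = np.asarray(allele_freq, dtype=float).ravel()
        if p.size != M.shape[1]:
            raise ValueError("one allele frequency per marker required")
    else:
        p = M.mean(axis=0) / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    W = M - 2.0 * p if centered else M - 1.0
    A = W @ W.T / denom
    A[np.diag_indices_from(A)] += ridge
    ids = geno.dosage.index
    return GRM(A=pd.DataFrame(A, index=ids, columns=ids),
               denominator=denom,
               allele_freq=pd.Series(p, index=geno.dosage.columns),
               ridge=ridge)


def subsample_markers(geno: GenotypeMatrix, n_or_fraction,
                      seed: int | None = None) -> GenotypeMatrix:
    """Uniform random marker subset without replacement (reproducible)."""
    m = geno.n_markers
    if isinstance(n_or_fraction, float) and n_or_fraction <= 1.0:
        n = int(round(n_or_fraction * m))
    else:
        n = int(n_or_fraction)
    if n > m:
        raise ValueError(f"requested {n} markers but only {m} available")
    if n == m:
        return GenotypeMatrix(geno.dosage.copy(), geno.markers.copy())
    rng = np.random.default_rng(seed)
    keep = np.zeros(m, dtype=bool)
    keep[rng.choice(m, size=n, replace=False)] = True
    return geno._subset_markers(keep)
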
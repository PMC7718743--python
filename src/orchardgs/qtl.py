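"""Genome scans for QTL with permutation-derived significance.

A marker-based scan with forward-selected cofactors stands in for full
composite interval mapping: markers in biparental populations are dense
relative to the genetic map, so testing at markers (rather than walking
intervals) loses little positional resolution while keeping the scan a
pure linear-model computation.  Per marker m outside the cofactor windows,

    LOD(m) = (n / 2) * log10(RSS_cofactors / RSS_cofactors+m),

and significance comes from the empirical (1 - alpha) quantile of the
genome-wide maximum LOD over phenotype permutations (permuting y jointly
against the whole genotype matrix preserves marker LD).  QTL detection is
iterative: scan, promote the top marker above the threshold to cofactor
(masking a window around it), rescan, stop when nothing exceeds the
threshold; peak R2 values come from the joint multi-QTL linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["ScanResult", "genome_scan", "permutation_threshold", "detect_qtl",
           "select_tag_qtl"]


@dataclass
class ScanResult:
    """Per-marker LOD profile with (optionally) threshold and called peaks."""

    lod: pd.Series                      # marker -> LOD (NaN where excluded)
    cofactors: tuple = ()
    threshold: float | None = None
    alpha: float | None = None
    n_perm: int | None = None
    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path) -> None:
        df = self.lod.rename("lod").to_frame()
        df.to_csv(path, sep="\t", index_label="marker")


def _scan_matrix(geno: GenotypeMatrix, cofactors, window: float):
    """Design pieces for a scan: marker matrix, exclusion mask, projector."""
    M = geno.dosage.to_numpy(dtype=float)
    n = M.shape[0]
    cols = list(geno.dosage.columns)
    poscol = geno.position_column()
    pos = geno.markers[poscol].to_numpy(dtype=float)
    chrom = geno.markers["chrom"].to_numpy()

    excluded = np.zeros(M.shape[1], dtype=bool)
    Xc = [np.ones((n, 1))]
    for cf in cofactors:
        j = cols.index(cf)
        excluded |= (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window)
        Xc.append(M[:, [j]])
    X = np.hstack(Xc)
    Q, _ = np.linalg.qr(X)
    return M, excluded, Q


def _lod_profile(y_res: np.ndarray, M_res: np.ndarray, n: int) -> np.ndarray:
    """Vectorized LOD over residualized markers for one (residualized) y."""
    ss_m = np.einsum("ij,ij->j", M_res, M_res)
    ss_y = float(y_res @ y_res)
    num = M_res.T @ y_res
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_m > 1e-12, num ** 2 / (ss_m * ss_y), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    return -(n / 2.0) * np.log10(1.0 - r2)


def genome_scan(y, geno: GenotypeMatrix, cofactors=(),
                window: float = 10.0) -> ScanResult:
    """Single-marker scan of one trait, conditioning on cofactor markers.

    Markers within ``window`` map units of a cofactor (same chromosome) are
    excluded from the scan (LOD = NaN); markers constant after imputation
    get LOD 0.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(geno.individuals).to_numpy()
    y = np.asarray(y, dtype=float).ravel()
    n = geno.n_individuals
    if y.size != n:
        raise ValueError("y must be indexed by the genotyped individuals")
    M, excluded, Q = _scan_matrix(geno, cofactors, window)
    y_res = y - Q @ (Q.T @ y)
    M_res = M - Q @ (Q.T @ M)
    lod = _lod_profile(y_res, M_res, n)
    lod[excluded] = np.nan
    return ScanResult(lod=pd.Series(lod, index=geno.dosage.columns),
                      cofactors=tuple(cofactors))


def permutation_threshold(y, geno: GenotypeMatrix, n_perm: int = 1000,
                          alpha: float = 0.01, seed=None, cofactors=(),
                          window: float = 10.0) -> float:
    """Empirical genome-wide LOD threshold from phenotype permutations.

    The threshold is the (1 - alpha) quantile of the max-LOD null
    distribution; permutations shuffle y jointly against all markers.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable quantile")
    if alpha * n_perm < 1:
        import warnings
        warnings.warn("alpha * n_perm < 1: threshold quantile is unstable")
    if isinstance(y, pd.Series):
        y = y.reindex(geno.individuals).to_numpy()
    y = np.asarray(y, dtype=float).ravel()
    n = geno.n_individuals
    M, excluded, Q = _scan_matrix(geno, cofactors, window)
    M_res = M - Q @ (Q.T @ M)
    M_res = M_res[:, ~excluded]
    rng = np.random.default_rng(seed)
    # all permutations at once: columns of Yp are permuted phenotypes
    Yp = np.empty((n, n_perm))
    for b in range(n_perm):
        Yp[:, b] = y[rng.permutation(n)]
    Yp -= Q @ (Q.T @ Yp)
    ss_m = np.einsum("ij,ij->j", M_res, M_res)
    ss_y = np.einsum("ij,ij->j", Yp, Yp)
    num = M_res.T @ Yp  # markers x perms
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = num ** 2 / np.outer(np.where(ss_m > 1e-12, ss_m, np.inf), ss_y)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
    max_lod = (-(n / 2.0) * np.log10(1.0 - r2)).max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha))


def detect_qtl(y, geno: GenotypeMatrix, n_perm: int = 1000,
               alpha: float = 0.01, seed=None, window: float = 10.0,
               max_qtl: int = 5) -> ScanResult:
    """Iterative QTL detection with a permutation threshold.

    Forward selection promotes the strongest marker above the genome-wide
    threshold to cofactor and rescans, up to ``max_qtl`` peaks (and never
    more than n/3, a guard against runaway selection).  Peak R2 is the
    partial variance explained in the joint linear model over all peaks.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(geno.individuals).to_numpy()
    y = np.asarray(y, dtype=float).ravel()
    n = geno.n_individuals
    thr = permutation_threshold(y, geno, n_perm=n_perm, alpha=alpha, seed=seed,
                                window=window)
    cap = min(max_qtl, n // 3)
    cofactors: list = []
    peak_lod: dict = {}
    while len(cofactors) < cap:
        scan = genome_scan(y, geno, cofactors=cofactors, window=window)
        lod = scan.lod.dropna()
        if lod.empty or lod.max() < thr:
            break
        top = lod.idxmax()
        peak_lod[top] = float(lod.max())
        cofactors.append(top)

    final = genome_scan(y, geno, window=window)  # unconditioned profile
    peaks = _joint_peaks(y, geno, cofactors, peak_lod, thr)
    return ScanResult(lod=final.lod, cofactors=tuple(cofactors),
                      threshold=thr, alpha=alpha, n_perm=n_perm, peaks=peaks)


def select_tag_qtl(peaks: pd.DataFrame, dosage: pd.DataFrame,
                   max_corr: float = 0.5, cap: int = 5,
                   min_r2: float = 0.0) -> list:
    """Pick one tag SNP per distinct QTL for use as fixed covariates.

    Peaks are taken in decreasing LOD order; a peak is kept only if its
    dosage correlates below ``max_corr`` with every already-kept tag, so a
    single broad region (LD in an F1 cross spans tens of cM) contributes
    one covariate rather than several near-duplicates.
    """
    keep: list = []
    if peaks is None or len(peaks) == 0:
        return keep
    for _, row in peaks.sort_values("lod", ascending=False).iterrows():
        if row.get("r2", 1.0) < min_r2:
            continue
        m = row["marker"]
        x = dosage[m].to_numpy(dtype=float)
        ok = True
        for k in keep:
            z = dosage[k].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(z) == 0 \
                    or abs(np.corrcoef(x, z)[0, 1]) >= max_corr:
                ok = False
                break
        if ok:
            keep.append(m)
        if len(keep) >= cap:
            break
    return keep


def _joint_peaks(y, geno, markers, lod, thr) -> pd.DataFrame:
    if not markers:
        return pd.DataFrame(columns=["marker", "chrom", "pos", "lod", "r2"])
    n = len(y)
    Mq = geno.dosage[markers].to_numpy(dtype=float)
    X = np.hstack([np.ones((n, 1)), Mq])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ beta) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    rows = []
    poscol = geno.position_column()
    for k, m in enumerate(markers):
        Xr = np.delete(X, k + 1, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_r = float(np.sum((y - Xr @ br) ** 2))
        rows.append({
            "marker": m,
            "chrom": geno.markers.loc[m, "chrom"],
            "pos": geno.markers.loc[m, poscol],
            "lod": float(lod[m]),
            "r2": max(0.0, (rss_r - rss_full) / tss)})
    return pd.DataFrame(rows)
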
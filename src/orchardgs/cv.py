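"""Cross-validation engine for genomic prediction experiments.

Replicated random 75/25 partitions (100 replicates by default): the model
is trained on the training partition's adjusted phenotypes and judged by
the Pearson correlation between predicted and observed values in the
validation partition.  Scenarios sweep the experimental factors —
prediction model, training-population size, marker density, fold-wise QTL
detection for the QTL-as-fixed-covariates model, and focal-trait missing
rate (delegated to :mod:`orchardgs.multitrait`).

Each replicate draws a fresh independent partition without duplicating
individuals; a bootstrap-training mode (sampling the training set with
replacement) is available behind a flag for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CVConfig", "CVReport", "GSData", "make_partition",
           "prediction_accuracy", "run_scenario", "summarize"]


@dataclass
class GSData:
    """Bundle of aligned inputs for a prediction experiment.

    ``geno``: imputed GenotypeMatrix; ``phenos``: genotype x trait adjusted
    values; ``grm``: optional precomputed GRM (built on demand).
    """

    geno: object
    phenos: pd.DataFrame
    grm: object = None

    def __post_init__(self):
        common = self.geno.dosage.index.intersection(self.phenos.index)
        if len(common) < len(self.geno.dosage.index):
            logger.info("aligning on %d common individuals", len(common))
        self.geno = type(self.geno)(self.geno.dosage.loc[common],
                                    self.geno.markers)
        self.phenos = self.phenos.loc[common]


@dataclass
class CVConfig:
    """Cross-validation configuration (defaults mirror a 75/25 x 100 design)."""

    trait: str = None
    model: str = "RRBLUP"
    scenario: str = "baseline"  # baseline | qtl_fixed | tp_size | marker_density
    train_fraction: float = 0.75
    n_replicates: int = 100
    seed: int = 0
    tp_sizes: tuple = (43, 76, 115)
    marker_numbers: tuple = ()       # absolute SNP counts, e.g. (50, 100)
    marker_fractions: tuple = ()     # fractions of the full panel
    qtl_alpha: float = 0.01
    qtl_n_perm: int = 200
    max_qtl: int = 5
    # fold-wise scans use a wide exclusion window and a tag-correlation cap:
    # LD in an F1 cross decays slowly, so nearby "peaks" tag the same QTL
    qtl_window: float = 30.0
    qtl_tag_max_corr: float = 0.5
    bootstrap_training: bool = False
    chain: object = None             # ChainSettings for Bayesian models

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class CVReport:
    """Per-replicate accuracies plus the factor levels they were run at."""

    records: pd.DataFrame
    factors: tuple = ()

    def summarize(self) -> pd.DataFrame:
        return summarize(self)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def make_partition(ids, train_fraction: float, seed=None):
    """Disjoint, exhaustive random split; training size = floor(n * fraction)."""
    ids = pd.Index(ids)
    n = len(ids)
    if n < 8:
        raise ValueError("need at least 8 individuals to partition")
    n_train = int(np.floor(n * train_fraction))
    if n_train < 5:
        raise ValueError("training set would have fewer than 5 individuals")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return ids[perm[:n_train]], ids[perm[n_train:]]


def prediction_accuracy(gebv_val, y_val) -> float:
    """Pearson correlation between predicted and observed validation values.

    Returns NaN (recorded as missing, not zero) when either vector is
    constant or fewer than 3 pairs remain.
    """
    x = np.asarray(gebv_val, dtype=float).ravel()
    y = np.asarray(y_val, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _fit_predict(y_tr, geno_tr, geno_val, model, chain, qtl_ids=None):
    """Train one model and return validation GEBVs."""
    from .genotypes import compute_grm
    from .wgr import BayesianAlphabet, ChainSettings, GBLUP, RidgeBLUP, \
        fit_qtl_fixed

    Z_tr, Z_val = geno_tr.dosage, geno_val.dosage
    if qtl_ids is not None:
        fit = fit_qtl_fixed(y_tr, Z_tr, qtl_ids)
        return fit.predict(Z_val)
    if model == "RRBLUP":
        return RidgeBLUP(y_tr, Z_tr).fit().predict(Z_val)
    if model == "GBLUP":
        # GRM over train+validation so cross-relationships are consistent
        from .genotypes import GenotypeMatrix
        both = GenotypeMatrix(pd.concat([Z_tr, Z_val]), geno_tr.markers)
        A = compute_grm(both).A
        fit = GBLUP(y_tr, A.loc[Z_tr.index, Z_tr.index]).fit()
        return fit.predict(K_cross=A.loc[Z_val.index, Z_tr.index])
    if model in ("BRR", "BayesA", "BayesB", "BayesC", "BL"):
        chain = chain or ChainSettings(n_iter=3000, burn_in=500, thin=2)
        fit = BayesianAlphabet(y_tr, Z_tr, model=model, chain=chain).fit()
        # predict on the same centered scale the sampler used
        Zc = Z_val.to_numpy(float) - geno_tr.dosage.to_numpy(float).mean(axis=0)
        return Zc @ fit.u
    raise ValueError(f"unknown model {model!r}")


def _subset_geno(geno, ids):
    from .genotypes import GenotypeMatrix
    return GenotypeMatrix(geno.dosage.loc[ids], geno.markers)


def run_scenario(cfg: CVConfig, data: GSData) -> CVReport:
    """Run a cross-validation scenario; returns per-replicate accuracies.

    Replicate failures are recorded and skipped; the run aborts if more
    than 20% of replicates fail.
    """
    from .qtl import detect_qtl
    from .genotypes import subsample_markers

    y = data.phenos[cfg.trait] if cfg.trait else data.phenos.iloc[:, 0]
    ids = data.geno.dosage.index
    rng = np.random.default_rng(cfg.seed)
    rows, failures = [], 0
    factors: tuple

    for rep in range(cfg.n_replicates):
        rep_seed = int(rng.integers(2 ** 31))
        try:
            rows.extend(_one_replicate(cfg, data, y, ids, rep, rep_seed))
        except Exception as err:  # noqa: BLE001 - replicate isolation
            failures += 1
            logger.warning("replicate %d failed: %s", rep, err)
            if failures > 0.2 * cfg.n_replicates:
                raise RuntimeError(
                    f"{failures} replicate failures (> 20%); aborting") from err
    factors = {"baseline": ("model",), "qtl_fixed": ("method",),
               "tp_size": ("tp_size",),
               "marker_density": ("n_markers",)}[cfg.scenario]
    return CVReport(records=pd.DataFrame(rows), factors=factors)


def _one_replicate(cfg, data, y, ids, rep, rep_seed):
    from .qtl import detect_qtl
    from .genotypes import subsample_markers

    rng = np.random.default_rng(rep_seed)
    rows = []

    if cfg.scenario == "tp_size":
        for size in cfg.tp_sizes:
            if size >= len(ids):
                raise ValueError(f"tp size {size} >= population {len(ids)}")
            perm = rng.permutation(len(ids))
            train, val = ids[perm[:size]], ids[perm[size:]]
            gebv = _fit_predict(y.loc[train], _subset_geno(data.geno, train),
                                _subset_geno(data.geno, val),
                                cfg.model, cfg.chain)
            rows.append({"replicate": rep, "tp_size": size, "model": cfg.model,
                         "accuracy": prediction_accuracy(gebv, y.loc[val])})
        return rows

    train, val = make_partition(ids, cfg.train_fraction,
                                int(rng.integers(2 ** 31)))
    if cfg.bootstrap_training:
        train = pd.Index(rng.choice(train, size=len(train), replace=True))
    g_tr, g_val = _subset_geno(data.geno, train), _subset_geno(data.geno, val)
    y_tr, y_val = y.loc[train], y.loc[val]

    if cfg.scenario == "baseline":
        gebv = _fit_predict(y_tr, g_tr, g_val, cfg.model, cfg.chain)
        rows.append({"replicate": rep, "model": cfg.model,
                     "accuracy": prediction_accuracy(gebv, y_val)})
    elif cfg.scenario == "marker_density":
        m = data.geno.n_markers
        numbers = list(cfg.marker_numbers) + \
            [max(1, int(round(f * m))) for f in cfg.marker_fractions]
        for nm in numbers:
            sub_seed = int(rng.integers(2 ** 31))
            g_tr_s = subsample_markers(g_tr, nm, seed=sub_seed)
            g_val_s = subsample_markers(g_val, nm, seed=sub_seed)
            gebv = _fit_predict(y_tr, g_tr_s, g_val_s, cfg.model, cfg.chain)
            rows.append({"replicate": rep, "n_markers": nm, "model": cfg.model,
                         "accuracy": prediction_accuracy(gebv, y_val)})
    elif cfg.scenario == "qtl_fixed":
        base = _fit_predict(y_tr, g_tr, g_val, cfg.model, cfg.chain)
        rows.append({"replicate": rep, "method": "baseline",
                     "accuracy": prediction_accuracy(base, y_val)})
        scan = detect_qtl(y_tr, g_tr, n_perm=cfg.qtl_n_perm,
                          alpha=cfg.qtl_alpha,
                          seed=int(rng.integers(2 ** 31)),
                          max_qtl=cfg.max_qtl, window=cfg.qtl_window)
        from .qtl import select_tag_qtl
        qtl = select_tag_qtl(scan.peaks, g_tr.dosage,
                             max_corr=cfg.qtl_tag_max_corr, cap=cfg.max_qtl)
        gebv = _fit_predict(y_tr, g_tr, g_val, cfg.model, cfg.chain,
                            qtl_ids=qtl) if qtl else base
        rows.append({"replicate": rep, "method": "qtl_fixed",
                     "n_qtl": len(qtl),
                     "accuracy": prediction_accuracy(gebv, y_val)})
    else:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    return rows


def summarize(report: CVReport) -> pd.DataFrame:
    """Mean and SD of accuracy per factor cell (missing values excluded)."""
    df = report.records
    if df.empty:
        raise ValueError("empty report")
    keys = [f for f in report.factors if f in df.columns]
    grouped = df.groupby(keys) if keys else df.groupby(lambda _: "all")
    out = grouped["accuracy"].agg(
        mean="mean",
        sd=lambda s: 0.0 if s.notna().sum() == 1 else s.std(ddof=1),
        n_used=lambda s: s.notna().sum(),
        n_missing=lambda s: s.isna().sum())
    out["single_replicate"] = out["n_used"] == 1
    return out.reset_index()
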
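"""Phenotype adjustment for multi-year, multi-lot orchard trials.

Raw fruit-quality records carry year effects, maturity-lot (firmness batch)
effects and genotype-by-year interaction on top of the genotypic signal.
Two companion mixed models are fitted per trait:

* the *adjustment model* — genotype and genotype-by-year random, year and
  lot fixed — whose genotype BLUPs (plus the overall mean) are the adjusted
  genetic values passed to QTL scans and genomic prediction;
* an *all-random model* — genotype, year, lot and genotype-by-year all
  random — supplying the variance components entering the broad-sense
  heritability on a genotype-mean basis:

  ``H2 = s2_g / (s2_g + s2_gy/ny + s2_l/nl + s2_y/ny + s2_e/(ny*nl))``

Also here: CIELAB hue angle from chromaticity coordinates, the log
transform used for strongly right-skewed traits such as ethylene
production, and pairwise trait correlations on adjusted values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._reml import VarianceComponentREML

logger = logging.getLogger(__name__)

__all__ = ["hue_angle", "transform_ethylene", "inverse_transform_ethylene",
           "VarianceComponents", "broad_sense_heritability",
           "PhenotypeAdjustment", "AdjustmentResults", "adjust_all_traits",
           "pairwise_trait_correlations", "read_phenotypes"]


def hue_angle(a_star, b_star):
    """Hue angle (degrees, quadrant-correct) from CIELAB a*, b* coordinates."""
    a = np.asarray(a_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if np.any((a == 0) & (b == 0)):
        raise ValueError("hue angle undefined at (a*, b*) = (0, 0)")
    return np.degrees(np.arctan2(b, a))


def transform_ethylene(values, offset: float = 1.0):
    """Natural-log transform for right-skewed rate traits: log(x + offset).

    The default offset of 1 tolerates exact zeros (no measurable
    production during confinement).
    """
    x = np.asarray(values, dtype=float) + offset
    if np.any(x[~np.isnan(x)] <= 0):
        raise ValueError("non-positive value after offset; increase offset")
    return np.log(x)


def inverse_transform_ethylene(values, offset: float = 1.0):
    return np.exp(np.asarray(values, dtype=float)) - offset


@dataclass
class VarianceComponents:
    """Variance components of the all-random trial model (trait units squared)."""

    sigma2_g: float
    sigma2_gy: float
    sigma2_y: float
    sigma2_l: float
    sigma2_e: float
    n_years: int
    n_lots: int


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """Genotype-mean-basis broad-sense heritability from trial components."""
    if vc.n_years < 1 or vc.n_lots < 1:
        raise ValueError("need at least one year and one lot")
    denom = (vc.sigma2_g + vc.sigma2_gy / vc.n_years + vc.sigma2_l / vc.n_lots
             + vc.sigma2_y / vc.n_years + vc.sigma2_e / (vc.n_years * vc.n_lots))
    if denom <= 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return vc.sigma2_g / denom


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype CSV (genotype, year, lot, trait, value)."""
    df = pd.read_csv(path)
    required = {"genotype", "year", "lot", "trait", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(required)}")
    return df


def _dummies(codes: pd.Series) -> np.ndarray:
    return pd.get_dummies(codes).to_numpy(dtype=float)


class PhenotypeAdjustment:
    """Mixed-model phenotype adjustment for one trait.

    Parameters
    ----------
    table : long-format records with columns genotype, year, lot, value
        (pre-filtered to one trait, or pass ``trait`` to select).
    trait : optional trait name to select from a multi-trait table.
    """

    def __init__(self, table: pd.DataFrame, trait: str | None = None):
        df = table
        if trait is not None:
            df = df[df["trait"] == trait]
        df = df.dropna(subset=["value"]).copy()
        if not np.isfinite(df["value"]).all():
            raise ValueError("non-finite phenotype values")
        dup = df.duplicated(subset=["genotype", "year", "lot"])
        if dup.any():
            raise ValueError("more than one record per (genotype, year, lot) cell")
        counts = df.groupby("genotype").size()
        dropped = counts[counts == 0].index
        if len(dropped):
            logger.warning("dropping %d genotypes without records", len(dropped))
        if df["genotype"].nunique() < 2:
            raise ValueError("need at least two genotypes")
        self.table = df
        self.trait = trait

    def fit(self) -> "AdjustmentResults":
        df = self.table
        y = df["value"].to_numpy(dtype=float)
        Zg = _dummies(df["genotype"])
        # get_dummies sorts levels; keep the same order for BLUP labels
        genotypes = pd.Index(sorted(df["genotype"].unique()))
        ny = df["year"].nunique()
        nl = df["lot"].nunique()

        if ny == 1 and nl == 1:
            warnings.warn("single year and lot: falling back to genotype means")
            means = df.groupby("genotype")["value"].mean()
            mu = float(y.mean())
            adj = means.reindex(genotypes)
            vc = VarianceComponents(float(adj.var(ddof=1)), 0.0, 0.0, 0.0,
                                    0.0, ny, nl)
            return AdjustmentResults(self.trait, adj, vc, mu,
                                     blups=adj - mu, converged=True,
                                     adjustment_varcomps={})

        # adjustment model: year/lot fixed, genotype and G x Y random
        X_parts = [np.ones((len(df), 1))]
        if ny > 1:
            X_parts.append(_dummies(df["year"])[:, 1:])
        if nl > 1:
            X_parts.append(_dummies(df["lot"])[:, 1:])
        X = np.hstack(X_parts)
        random = {"genotype": Zg}
        if ny > 1:
            random["gxy"] = _dummies(df["genotype"].astype(str) + ":"
                                     + df["year"].astype(str))
        adj_fit = VarianceComponentREML(y, X, random).fit()
        mu = float((X @ adj_fit.beta).mean())
        blups = pd.Series(adj_fit.blups["genotype"], index=genotypes)
        adjusted = mu + blups

        # companion all-random model for the H2 components
        random_all = {"genotype": Zg}
        if ny > 1:
            random_all["year"] = _dummies(df["year"])
        if nl > 1:
            random_all["lot"] = _dummies(df["lot"])
        if ny > 1:
            random_all["gxy"] = random["gxy"]
        allr = VarianceComponentREML(y, np.ones((len(df), 1)), random_all).fit()
        vc = VarianceComponents(
            sigma2_g=allr.variances.get("genotype", 0.0),
            sigma2_gy=allr.variances.get("gxy", 0.0),
            sigma2_y=allr.variances.get("year", 0.0),
            sigma2_l=allr.variances.get("lot", 0.0),
            sigma2_e=allr.sigma_e2, n_years=ny, n_lots=nl)
        converged = adj_fit.converged and allr.converged
        if not converged:
            logger.warning("REML did not converge for trait %r", self.trait)
        return AdjustmentResults(self.trait, adjusted, vc, mu, blups,
                                 converged,
                                 adjustment_varcomps={**adj_fit.variances,
                                                      "residual": adj_fit.sigma_e2})


@dataclass
class AdjustmentResults:
    """Adjusted genetic values and variance components for one trait."""

    trait: str | None
    adjusted: pd.Series  # genotype -> mu + BLUP
    varcomps: VarianceComponents
    mu: float
    blups: pd.Series
    converged: bool
    adjustment_varcomps: dict

    @property
    def H2(self) -> float:
        return broad_sense_heritability(self.varcomps)

    def summary(self) -> str:
        vc = self.varcomps
        lines = [
            f"Phenotype adjustment — trait: {self.trait or '(unnamed)'}",
            f"  genotypes: {len(self.adjusted)}   years: {vc.n_years}"
            f"   lots: {vc.n_lots}   converged: {self.converged}",
            f"  sigma2_g  = {vc.sigma2_g:10.4f}",
            f"  sigma2_gy = {vc.sigma2_gy:10.4f}",
            f"  sigma2_y  = {vc.sigma2_y:10.4f}",
            f"  sigma2_l  = {vc.sigma2_l:10.4f}",
            f"  sigma2_e  = {vc.sigma2_e:10.4f}",
            f"  broad-sense H2 (genotype-mean basis) = {self.H2:.3f}",
        ]
        return "\n".join(lines)


def adjust_all_traits(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Adjust every trait in a long-format table.

    Returns (genotype x trait DataFrame of adjusted values,
    dict trait -> AdjustmentResults).
    """
    results = {}
    cols = {}
    for trait in table["trait"].unique():
        res = PhenotypeAdjustment(table, trait).fit()
        results[trait] = res
        cols[trait] = res.adjusted
    return pd.DataFrame(cols), results


def pairwise_trait_correlations(adjusted: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between traits on genotype-level adjusted values.

    Zero-variance traits yield NaN rows/columns (flagged by a warning).
    """
    if adjusted.shape[0] < 3:
        raise ValueError("need at least 3 genotypes")
    sd = adjusted.std(ddof=1)
    if (sd == 0).any():
        warnings.warn("zero-variance trait(s): "
                      + ", ".join(adjusted.columns[sd == 0].astype(str)))
    corr = adjusted.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    corr[sd == 0] = np.nan
    corr.loc[sd == 0] = np.nan
    return corr
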
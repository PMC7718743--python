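"""Whole-genome regression models for genomic prediction.

The six model families used in genomic selection of biparental fruit-tree
populations, presented statsmodels-style (a model object built from data,
``fit()`` returning a results object):

* :class:`RidgeBLUP` — RR-BLUP: all markers random with one common variance,
  variance ratio estimated by spectral REML, effects by the kernel identity
  ``u = Z'(ZZ' + lambda I)^-1 (y - X beta)``;
* :class:`GBLUP` — the marker-equivalent kernel model with a genomic
  relationship matrix as covariance of genetic values;
* :class:`BayesianAlphabet` — BayesA, BayesB, BayesC, Bayesian LASSO (BL)
  and Bayesian ridge regression (BRR) by Gibbs sampling with conjugate
  full conditionals (see ``_samplers``).

GEBVs are the sum of estimated marker effects times allelic dosages (plus
the fixed QTL-covariate contribution when the genetic architecture is
supplied through :func:`fit_qtl_fixed`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import _samplers
from ._reml import reml_kernel

__all__ = ["ChainSettings", "WGRResults", "RidgeBLUP", "GBLUP",
           "BayesianAlphabet", "fit_qtl_fixed", "BAYESIAN_MODELS"]

BAYESIAN_MODELS = ("BRR", "BayesA", "BayesB", "BayesC", "BL")
_MODEL_CODES = {"BRR": _samplers.BRR, "BayesA": _samplers.BAYES_A,
                "BayesB": _samplers.BAYES_B, "BayesC": _samplers.BAYES_C,
                "BL": _samplers.BL}


@dataclass
class ChainSettings:
    """Gibbs chain settings (defaults for production runs; tests scale down)."""

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class WGRResults:
    """A fitted whole-genome regression.

    ``u`` holds marker effects (marker-based models; None for GBLUP, whose
    genetic values live in ``g``).  ``predict`` computes validation GEBVs
    from dosages (marker models) or from cross-relationship rows of the
    GRM (GBLUP).
    """

    model: str
    beta: np.ndarray                 # fixed effects (intercept first)
    sigma_u2: float
    sigma_e2: float
    g: np.ndarray                    # genetic values, training individuals
    u: np.ndarray | None = None      # marker effects
    marker_ids: pd.Index | None = None
    qtl_ids: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)
    _kernel_alpha: np.ndarray | None = None  # (K + delta I)^-1 resid, GBLUP

    @property
    def heritability(self) -> float:
        """Genomic heritability proxy sigma_u2/(sigma_u2+sigma_e2) (kernel
        models only; for marker models it is the per-marker variance)."""
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.beta[0] + self.g

    def predict(self, Z_val=None, K_cross=None) -> np.ndarray:
        """GEBVs for validation individuals.

        Marker-based fits take a dosage matrix ``Z_val`` (columns must match
        the training markers when both carry ids); GBLUP takes ``K_cross``,
        the validation x training block of the relationship matrix.
        """
        if self.u is not None:
            if Z_val is None:
                raise ValueError("marker-based fit needs validation dosages")
            if isinstance(Z_val, pd.DataFrame) and self.marker_ids is not None:
                missing = [m for m in self.marker_ids if m not in Z_val.columns]
                if missing:
                    raise ValueError(f"validation dosages lack markers: {missing[:5]}"
                                     + ("..." if len(missing) > 5 else ""))
                Zq = Z_val[self.qtl_ids].to_numpy(float) if self.qtl_ids else None
                Z_val = Z_val[self.marker_ids].to_numpy(float)
            else:
                Zq = None
                Z_val = np.asarray(Z_val, dtype=float)
            gebv = Z_val @ self.u
            if self.qtl_ids:
                if Zq is None:
                    raise ValueError("QTL-fixed fit needs a DataFrame with "
                                     "named markers for prediction")
                gebv = gebv + Zq @ self.beta[1:1 + len(self.qtl_ids)]
            return gebv
        if K_cross is None:
            raise ValueError("GBLUP prediction needs cross-relationship rows")
        K_cross = K_cross.to_numpy() if hasattr(K_cross, "to_numpy") else K_cross
        return np.asarray(K_cross) @ self._kernel_alpha

    def summary(self) -> str:
        lines = [f"Whole-genome regression — model: {self.model}",
                 f"  intercept        = {self.beta[0]:.4f}",
                 f"  sigma_u^2        = {self.sigma_u2:.6g}",
                 f"  sigma_e^2        = {self.sigma_e2:.6g}"]
        if self.qtl_ids:
            lines.append(f"  fixed QTL covariates: {len(self.qtl_ids)}")
        for k, v in self.extras.items():
            if np.isscalar(v):
                lines.append(f"  {k:<16} = {v:.4g}" if isinstance(v, float)
                             else f"  {k:<16} = {v}")
        lines.append(f"  training individuals = {len(self.g)}")
        return "\n".join(lines)


def _prep_y_Z(y, Z):
    if isinstance(y, pd.Series):
        y = y.to_numpy()
    y = np.asarray(y, dtype=float).ravel()
    marker_ids = Z.columns if isinstance(Z, pd.DataFrame) else None
    Zv = Z.to_numpy(dtype=float) if isinstance(Z, pd.DataFrame) else \
        np.asarray(Z, dtype=float)
    if Zv.shape[0] != y.size:
        raise ValueError("y and Z have different numbers of individuals")
    if np.var(y) <= 0:
        raise ValueError("zero phenotypic variance")
    return y, Zv, marker_ids


class RidgeBLUP:
    """RR-BLUP: ``y = X beta + Z u + e`` with ``u ~ N(0, I sigma_u^2)``.

    The variance ratio is estimated by REML on the eigendecomposition of
    ``ZZ'``; marker effects come from the numerically equivalent kernel
    form, so cost scales with n, not the marker count.

    Parameters
    ----------
    y : adjusted phenotypes (length n).
    Z : n x p dosage design (DataFrame keeps marker ids for prediction).
    X : optional fixed-effect design; defaults to an intercept.
    """

    def __init__(self, y, Z, X=None):
        self.y, self.Z, self.marker_ids = _prep_y_Z(y, Z)
        if self.Z.shape[1] < 1:
            raise ValueError("need at least one marker")
        self.X = np.ones((self.y.size, 1)) if X is None else \
            np.atleast_2d(np.asarray(X, dtype=float))

    def fit(self, delta: float | None = None) -> WGRResults:
        """REML fit; pass ``delta`` to fix the variance ratio instead."""
        K = self.Z @ self.Z.T
        if delta is None:
            res = reml_kernel(self.y, K, self.X)
            delta, beta = res.delta, res.beta
            sigma_u2, sigma_e2 = res.sigma_u2, res.sigma_e2
            resid = res.resid
        else:
            n = self.y.size
            Vi = linalg.inv(K + delta * np.eye(n))
            XtViX = self.X.T @ Vi @ self.X
            beta = linalg.solve(XtViX, self.X.T @ Vi @ self.y)
            resid = self.y - self.X @ beta
            nf = n - self.X.shape[1]
            sigma_u2 = float(resid @ Vi @ resid) / nf
            sigma_e2 = sigma_u2 * delta
        alpha = linalg.solve(K + delta * np.eye(self.y.size), resid,
                             assume_a="pos")
        u = self.Z.T @ alpha
        return WGRResults(model="RRBLUP", beta=np.asarray(beta),
                          sigma_u2=sigma_u2, sigma_e2=sigma_e2,
                          g=self.Z @ u, u=u, marker_ids=self.marker_ids,
                          extras={"delta": float(delta)})


class GBLUP:
    """Kernel mixed model ``y = X beta + g + e``, ``g ~ N(0, sigma_u^2 K)``.

    ``K`` is typically a VanRaden GRM; marker-equivalent to RR-BLUP when K
    is built from the same centered markers.
    """

    def __init__(self, y, K, X=None):
        if isinstance(y, pd.Series):
            y = y.to_numpy()
        self.y = np.asarray(y, dtype=float).ravel()
        if hasattr(K, "A"):  # GRM dataclass
            K = K.A
        self.K = K.to_numpy() if hasattr(K, "to_numpy") else np.asarray(K, float)
        if self.K.shape != (self.y.size, self.y.size):
            raise ValueError("K must be n x n for the n phenotyped individuals")
        self.X = np.ones((self.y.size, 1)) if X is None else \
            np.atleast_2d(np.asarray(X, dtype=float))

    def fit(self) -> WGRResults:
        res = reml_kernel(self.y, self.K, self.X)
        alpha = linalg.solve(self.K + res.delta * np.eye(self.y.size),
                             res.resid, assume_a="pos")
        g = self.K @ alpha
        return WGRResults(model="GBLUP", beta=res.beta,
                          sigma_u2=res.sigma_u2, sigma_e2=res.sigma_e2,
                          g=g, _kernel_alpha=alpha,
                          extras={"delta": res.delta,
                                  "h2_genomic": res.heritability})


class BayesianAlphabet:
    """Bayesian whole-genome regression (BayesA/B/C, BL, BRR) via Gibbs.

    Priors follow common practice for these samplers: marker and residual
    variances carry scaled-inverse-chi-square priors with nu = 5 and scales
    set so the prior mode matches an assumed marker-explained R2 = 0.5 of
    the phenotypic variance; BayesB uses a fixed prior inclusion
    probability (pi = 0.95 of zero effects), BayesC treats pi as unknown
    with a Beta(1, 1) prior, and the LASSO's lambda^2 carries a Gamma
    hyperprior.  All are overridable.

    Markers are column-centered internally; the intercept is sampled.
    """

    def __init__(self, y, Z, model: str = "BayesA", *,
                 chain: ChainSettings | None = None,
                 pi: float | None = None, nu: float = 5.0,
                 r2: float = 0.5, update_variances: bool = True,
                 sigma_u2: float | None = None, sigma_e2: float | None = None,
                 bl_shape: float = 1.1, bl_rate: float | None = None):
        if model not in BAYESIAN_MODELS:
            raise ValueError(f"model must be one of {BAYESIAN_MODELS}")
        self.y, Zraw, self.marker_ids = _prep_y_Z(y, Z)
        self.Z = Zraw - Zraw.mean(axis=0)
        self.model = model
        self.chain = chain or ChainSettings()
        self.nu = nu
        self.r2 = r2
        self.update_variances = update_variances

        vy = float(np.var(self.y))
        msx = float(np.sum(self.Z.var(axis=0)))
        msx = max(msx, 1e-12)
        if pi is None:
            pi = 0.95 if model == "BayesB" else (0.5 if model == "BayesC" else 0.0)
        self.pi = float(pi)
        frac_in = max(1.0 - self.pi, 1e-3) if model in ("BayesB", "BayesC") else 1.0
        mode_var = r2 * vy / (msx * frac_in)
        self.S_u = sigma_u2 if sigma_u2 is not None \
            else mode_var * (nu + 2.0) / nu
        self.su2_init = sigma_u2 if sigma_u2 is not None else mode_var
        self.nu_e = 5.0
        self.S_e = (sigma_e2 if sigma_e2 is not None
                    else (1.0 - r2) * vy) * (self.nu_e + 2.0) / self.nu_e
        self.se2_init = sigma_e2 if sigma_e2 is not None else (1.0 - r2) * vy
        self._fixed_su2 = sigma_u2
        self._fixed_se2 = sigma_e2
        lambda2_init = 2.0 * (1.0 - r2) / max(r2, 1e-3) * msx
        self.bl_shape = bl_shape
        self.bl_rate = bl_rate if bl_rate is not None else bl_shape / lambda2_init
        self.lambda2_init = lambda2_init

    def fit(self) -> WGRResults:
        ch = self.chain
        update = self.update_variances and self._fixed_se2 is None
        out = _samplers.gibbs_wgr(
            self.y, self.Z, _MODEL_CODES[self.model],
            ch.n_iter, ch.burn_in, ch.thin, ch.seed,
            self.nu, self.S_u, self.nu_e, self.S_e,
            self.pi, self.model == "BayesC",
            update, self.su2_init, self.se2_init,
            self.bl_shape, self.bl_rate, self.lambda2_init)
        u, mu, se2, su2, pi_mean, incl, status = out
        if status != 0:
            raise RuntimeError(
                f"{self.model} chain diverged (non-finite residual variance); "
                f"chain={ch}, priors S_u={self.S_u:.3g}, S_e={self.S_e:.3g}")
        extras = {"pi": pi_mean, "chain": ch,
                  "inclusion_prob": incl}
        if self.model == "BL":
            extras["lambda2"] = su2
        return WGRResults(model=self.model, beta=np.array([mu]),
                          sigma_u2=float(su2), sigma_e2=float(se2),
                          g=self.Z @ u, u=u, marker_ids=self.marker_ids,
                          extras=extras)


def fit_qtl_fixed(y, Z: pd.DataFrame, qtl_markers, model: str = "RRBLUP",
                  chain: ChainSettings | None = None) -> WGRResults:
    """Whole-genome regression with QTL-tagging SNPs as fixed covariates.

    The dosages of ``qtl_markers`` enter the fixed design alongside the
    intercept; the remaining markers stay random.  Duplicated ids are
    collapsed; collinear QTL columns are dropped (first in genome order
    wins).  An empty QTL list reduces exactly to the baseline model.
    """
    if not isinstance(Z, pd.DataFrame):
        raise TypeError("fit_qtl_fixed needs a DataFrame with marker ids")
    qtl = [m for i, m in enumerate(dict.fromkeys(qtl_markers))]
    missing = [m for m in qtl if m not in Z.columns]
    if missing:
        raise ValueError(f"QTL markers not in dosage matrix: {missing}")
    if not qtl:
        base = RidgeBLUP(y, Z) if model == "RRBLUP" else \
            BayesianAlphabet(y, Z, model=model, chain=chain)
        return base.fit()
    # genome order, then collinearity pruning by greedy QR rank check
    order = {m: i for i, m in enumerate(Z.columns)}
    qtl = sorted(qtl, key=order.get)
    n = len(Z)
    if len(qtl) >= n - 2:
        raise ValueError("too many QTL covariates for the training size")
    Xq_cols, kept = [np.ones((n, 1))], []
    for m in qtl:
        cand = np.hstack(Xq_cols + [Z[[m]].to_numpy(float)])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(np.hstack(Xq_cols)):
            Xq_cols.append(Z[[m]].to_numpy(float))
            kept.append(m)
        else:
            warnings.warn(f"dropping collinear QTL covariate {m!r}")
    X = np.hstack(Xq_cols)
    rest = [c for c in Z.columns if c not in set(kept)]
    Zr = Z[rest]
    if model == "RRBLUP":
        res = RidgeBLUP(y, Zr, X=X).fit()
    else:
        raise NotImplementedError(
            "the QTL-as-fixed-covariates model is paired with the RR-BLUP "
            "random term")
    res.qtl_ids = kept
    res.marker_ids = Zr.columns
    return res
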
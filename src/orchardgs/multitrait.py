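"""Bivariate genomic prediction and trait-assisted selection.

Two routes exploit an easy-to-measure proxy trait when predicting a focal
trait:

* :class:`BivariateGBLUP` — joint mixed model of the trait pair with
  ``u ~ N(0, Sigma_u (x) A)`` and ``e ~ N(0, Sigma_e (x) I)`` (residual
  covariance only between co-observed records of the same individual);
  missing focal phenotypes borrow information through the genetic and
  residual covariances.  REML by quasi-Newton on Cholesky-parameterized
  covariance matrices, so estimates are positive semi-definite by
  construction.
* :func:`model_based_index` — a two-stage selection index: single-trait
  GEBVs of the proxy enter the focal model as a fixed covariate (estimated
  by generalized least squares inside the mixed model), on top of a
  GRM-structured random effect.

:func:`missing_rate_experiment` masks focal phenotypes in the training
partition at increasing rates and records univariate, bivariate and
index accuracies per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from ._reml import reml_kernel
from .cv import CVReport, make_partition, prediction_accuracy
from .wgr import GBLUP

__all__ = ["BivariateGBLUP", "BivariateResults", "model_based_index",
           "predict_with_pheno_proxy", "missing_rate_experiment"]


def _chol_from_theta(t0, t1, t2):
    L = np.array([[np.exp(t0), 0.0], [t1, np.exp(t2)]])
    return L @ L.T


@dataclass
class BivariateResults:
    """REML estimates and genetic values from a bivariate GBLUP fit."""

    Sigma_u: np.ndarray
    Sigma_e: np.ndarray
    beta: np.ndarray              # per-trait intercepts
    genetic_values: pd.DataFrame  # all individuals x 2 traits
    loglik: float
    converged: bool

    @property
    def genetic_correlation(self) -> float:
        d = np.sqrt(self.Sigma_u[0, 0] * self.Sigma_u[1, 1])
        return float(self.Sigma_u[0, 1] / d) if d > 0 else np.nan

    def summary(self) -> str:
        rg = self.genetic_correlation
        re_ = self.Sigma_e[0, 1] / np.sqrt(self.Sigma_e[0, 0]
                                           * self.Sigma_e[1, 1] + 1e-300)
        return "\n".join([
            "Bivariate GBLUP",
            f"  Sigma_u = [[{self.Sigma_u[0,0]:.4f}, {self.Sigma_u[0,1]:.4f}],"
            f" [{self.Sigma_u[1,0]:.4f}, {self.Sigma_u[1,1]:.4f}]]",
            f"  Sigma_e = [[{self.Sigma_e[0,0]:.4f}, {self.Sigma_e[0,1]:.4f}],"
            f" [{self.Sigma_e[1,0]:.4f}, {self.Sigma_e[1,1]:.4f}]]",
            f"  genetic correlation  r_g = {rg:.3f}",
            f"  residual correlation r_e = {re_:.3f}",
            f"  REML log-likelihood = {self.loglik:.3f}"
            f"   converged: {self.converged}",
        ])


class BivariateGBLUP:
    """Joint GBLUP of a trait pair sharing a genomic relationship matrix.

    Parameters
    ----------
    y1, y2 : phenotypes aligned to the rows of ``K`` (pandas Series are
        reindexed to K's ids); NaN marks a missing record for that trait.
    K : n x n GRM (``GRM`` object, DataFrame or array).
    """

    def __init__(self, y1, y2, K):
        if hasattr(K, "A"):
            K = K.A
        self.ids = K.index if isinstance(K, pd.DataFrame) else None
        self.K = K.to_numpy() if hasattr(K, "to_numpy") else np.asarray(K, float)
        self.n = self.K.shape[0]

        def _vec(y):
            if isinstance(y, pd.Series) and self.ids is not None:
                y = y.reindex(self.ids)
            y = np.asarray(y, dtype=float).ravel()
            if y.size != self.n:
                raise ValueError("phenotypes must align with the GRM")
            return y

        self.y = [_vec(y1), _vec(y2)]
        self.obs = [np.isfinite(self.y[0]), np.isfinite(self.y[1])]
        for t in (0, 1):
            if self.obs[t].sum() < 3 or np.nanvar(self.y[t]) <= 0:
                raise ValueError(f"trait {t + 1} has too few records or no variance")

    # -- REML internals ---------------------------------------------------

    def _build_V(self, Su, Se):
        i0, i1 = self.obs
        K = self.K
        n0, n1 = i0.sum(), i1.sum()
        V = np.empty((n0 + n1, n0 + n1))
        V[:n0, :n0] = Su[0, 0] * K[np.ix_(i0, i0)] + Se[0, 0] * np.eye(n0)
        V[n0:, n0:] = Su[1, 1] * K[np.ix_(i1, i1)] + Se[1, 1] * np.eye(n1)
        C = Su[0, 1] * K[np.ix_(i0, i1)]
        # residual covariance only where both traits observed on the same tree
        both = np.flatnonzero(i0 & i1)
        r0 = np.searchsorted(np.flatnonzero(i0), both)
        r1 = np.searchsorted(np.flatnonzero(i1), both)
        C[r0, r1] += Se[0, 1]
        V[:n0, n0:] = C
        V[n0:, :n0] = C.T
        return V, n0, n1

    def _design(self, n0, n1):
        X = np.zeros((n0 + n1, 2))
        X[:n0, 0] = 1.0
        X[n0:, 1] = 1.0
        return X

    def _nll(self, theta, diag_only):
        with np.errstate(over="ignore", invalid="ignore"):
            if diag_only:
                Su = np.diag([np.exp(2 * theta[0]), np.exp(2 * theta[1])])
                Se = np.diag([np.exp(2 * theta[2]), np.exp(2 * theta[3])])
            else:
                Su = _chol_from_theta(theta[0], theta[1], theta[2])
                Se = _chol_from_theta(theta[3], theta[4], theta[5])
            if not (np.isfinite(Su).all() and np.isfinite(Se).all()):
                return np.inf
            V, n0, n1 = self._build_V(Su, Se)
        if not np.isfinite(V).all():
            return np.inf
        yobs = np.concatenate([self.y[0][self.obs[0]], self.y[1][self.obs[1]]])
        X = self._design(n0, n1)
        try:
            c, low = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        ViX = linalg.cho_solve((c, low), X, check_finite=False)
        Viy = linalg.cho_solve((c, low), yobs, check_finite=False)
        XtViX = X.T @ ViX
        try:
            with warnings.catch_warnings():
                # extreme trial parameters can make XtViX nearly singular;
                # the optimizer backtracks from the resulting poor objective
                warnings.simplefilter("ignore", linalg.LinAlgWarning)
                beta = linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
        except linalg.LinAlgError:
            return np.inf
        r = yobs - X @ beta
        Vir = linalg.cho_solve((c, low), r, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return 0.5 * (logdetV + logdetX + float(r @ Vir))

    def fit(self, diag_only: bool = False, maxiter: int = 500) -> BivariateResults:
        """REML fit; ``diag_only=True`` forces Sigma_u and Sigma_e diagonal.

        With both covariances diagonal the joint likelihood factorizes into
        the two univariate GBLUP likelihoods, so that case is fitted by its
        exact factorization (used for nesting and decoupling checks).
        """
        starts = []
        for t in (0, 1):
            yt = self.y[t][self.obs[t]]
            Kt = self.K[np.ix_(self.obs[t], self.obs[t])]
            try:
                r = reml_kernel(yt, Kt)
                starts.append((max(r.sigma_u2, 1e-9), max(r.sigma_e2, 1e-9)))
            except Exception:
                v = np.var(yt)
                starts.append((v / 2, v / 2))
        if diag_only:
            Su = np.diag([starts[0][0], starts[1][0]])
            Se = np.diag([starts[0][1], starts[1][1]])
            theta_eq = 0.5 * np.log([Su[0, 0], Su[1, 1], Se[0, 0], Se[1, 1]])
            loglik = -self._nll(theta_eq, True)
            res_success = True
        else:
            theta0 = np.array([0.5 * np.log(starts[0][0]), 0.0,
                               0.5 * np.log(starts[1][0]),
                               0.5 * np.log(starts[0][1]), 0.0,
                               0.5 * np.log(starts[1][1])])
            scale = 0.5 * np.log(max(np.nanvar(np.concatenate(
                [self.y[0][self.obs[0]], self.y[1][self.obs[1]]])), 1e-12))
            bounds = [(scale - 12.0, scale + 6.0), (-1e3, 1e3),
                      (scale - 12.0, scale + 6.0),
                      (scale - 12.0, scale + 6.0), (-1e3, 1e3),
                      (scale - 12.0, scale + 6.0)]
            res = optimize.minimize(self._nll, theta0, args=(False,),
                                    method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": maxiter, "ftol": 1e-11})
            th = res.x
            Su = _chol_from_theta(th[0], th[1], th[2])
            Se = _chol_from_theta(th[3], th[4], th[5])
            loglik = -float(res.fun)
            res_success = bool(res.success)

        V, n0, n1 = self._build_V(Su, Se)
        yobs = np.concatenate([self.y[0][self.obs[0]], self.y[1][self.obs[1]]])
        X = self._design(n0, n1)
        c, low = linalg.cho_factor(V)
        ViX = linalg.cho_solve((c, low), X)
        beta = linalg.solve(X.T @ ViX, ViX.T @ yobs, assume_a="pos")
        w = linalg.cho_solve((c, low), yobs - X @ beta)
        w0, w1 = w[:n0], w[n0:]
        K = self.K
        g = np.empty((self.n, 2))
        g[:, 0] = Su[0, 0] * K[:, self.obs[0]] @ w0 \
            + Su[0, 1] * K[:, self.obs[1]] @ w1
        g[:, 1] = Su[1, 0] * K[:, self.obs[0]] @ w0 \
            + Su[1, 1] * K[:, self.obs[1]] @ w1
        idx = self.ids if self.ids is not None else pd.RangeIndex(self.n)
        return BivariateResults(
            Sigma_u=Su, Sigma_e=Se, beta=np.asarray(beta),
            genetic_values=pd.DataFrame(g, index=idx,
                                        columns=["trait1", "trait2"]),
            loglik=float(loglik), converged=res_success)


def model_based_index(y_focal: pd.Series, proxy_gebv: pd.Series, K,
                      train) -> pd.Series:
    """Two-stage selection index: proxy GEBVs as a fixed covariate.

    ``y_focal`` must carry values for the training individuals; the proxy
    GEBVs (from a single-trait fit of the proxy) must cover training and
    validation individuals.  Returns GEBVs for every individual in K.

    A zero-variance proxy drops the covariate with a warning (plain GBLUP).
    """
    if hasattr(K, "A"):
        K = K.A
    ids = K.index
    Kv = K.to_numpy()
    train = pd.Index(train)
    ti = ids.get_indexer(train)
    if (ti < 0).any():
        raise ValueError("training individuals missing from the GRM")
    y_tr = y_focal.reindex(train).to_numpy(dtype=float)
    x_all = proxy_gebv.reindex(ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(x_all)):
        raise ValueError("proxy GEBVs must cover all individuals")
    x_tr = x_all[ti]

    if np.var(x_tr) <= 1e-12:
        warnings.warn("zero-variance proxy GEBVs: index reduces to GBLUP")
        X = np.ones((len(train), 1))
        use_proxy = False
    else:
        X = np.column_stack([np.ones(len(train)), x_tr])
        use_proxy = True
    K_tt = Kv[np.ix_(ti, ti)]
    r = reml_kernel(y_tr, K_tt, X)
    alpha = linalg.solve(K_tt + r.delta * np.eye(len(train)), r.resid,
                         assume_a="pos")
    g_all = Kv[:, ti] @ alpha
    out = g_all.copy()
    if use_proxy:
        out = out + x_all * r.beta[1]
    return pd.Series(out, index=ids)


def predict_with_pheno_proxy(y_focal: pd.Series, y_proxy: pd.Series, K,
                             train) -> pd.Series:
    """Bivariate GBLUP with focal phenotypes masked outside training.

    The proxy is phenotyped for everyone; validation individuals' focal
    genetic values are informed through the genetic (and residual)
    covariance with the proxy records.
    """
    if hasattr(K, "A"):
        K = K.A
    ids = K.index
    y1 = y_focal.reindex(ids).copy()
    y1[~ids.isin(pd.Index(train))] = np.nan
    fit = BivariateGBLUP(y1, y_proxy.reindex(ids), K).fit()
    return fit.genetic_values["trait1"]


def missing_rate_experiment(y_focal: pd.Series, y_proxy: pd.Series, K,
                            rates=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6,
                                   0.7, 0.8, 0.9),
                            n_reps: int = 100, seed=None,
                            train_fraction: float = 0.75) -> CVReport:
    """Sweep the focal-trait missing rate inside the training partition.

    Per replicate and rate: split 75/25, mask the focal trait for a random
    fraction of the *training* individuals, then record the validation
    accuracy of (i) univariate GBLUP on the unmasked focal records,
    (ii) the bivariate model with the proxy phenotyped for everyone, and
    (iii) the model-based index.  Rates leaving fewer than 5 focal records
    are skipped with a warning.
    """
    if hasattr(K, "A"):
        K = K.A
    ids = K.index
    Kv = K.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        train, val = make_partition(ids, train_fraction,
                                    rng.integers(2 ** 31))
        vi = ids.get_indexer(pd.Index(val))
        y_val = y_focal.reindex(pd.Index(val)).to_numpy(dtype=float)
        for rate in rates:
            if not (0 <= rate < 1):
                raise ValueError("rates must lie in [0, 1)")
            n_keep = len(train) - int(round(rate * len(train)))
            if n_keep < 5:
                warnings.warn(f"rate {rate} leaves {n_keep} focal records; skipped")
                continue
            kept = pd.Index(rng.choice(train, size=n_keep, replace=False))
            ki = ids.get_indexer(kept)

            # univariate GBLUP on unmasked focal records
            y_tr = y_focal.reindex(kept).to_numpy(dtype=float)
            r = reml_kernel(y_tr, Kv[np.ix_(ki, ki)])
            alpha = linalg.solve(Kv[np.ix_(ki, ki)]
                                 + r.delta * np.eye(len(kept)), r.resid,
                                 assume_a="pos")
            uni = Kv[np.ix_(vi, ki)] @ alpha
            rows.append({"replicate": rep, "rate": rate,
                         "method": "univariate",
                         "accuracy": prediction_accuracy(uni, y_val)})

            # bivariate with proxy observed everywhere
            biv = predict_with_pheno_proxy(y_focal.reindex(kept), y_proxy,
                                           K, kept)
            rows.append({"replicate": rep, "rate": rate,
                         "method": "multi_trait",
                         "accuracy": prediction_accuracy(
                             biv.iloc[vi].to_numpy(), y_val)})

            # model-based index: proxy GEBVs from the proxy's own records
            yp_tr = y_proxy.reindex(pd.Index(train)).to_numpy(dtype=float)
            tii = ids.get_indexer(pd.Index(train))
            rp = reml_kernel(yp_tr, Kv[np.ix_(tii, tii)])
            ap = linalg.solve(Kv[np.ix_(tii, tii)]
                              + rp.delta * np.eye(len(train)), rp.resid,
                              assume_a="pos")
            proxy_gebv = pd.Series(Kv[:, tii] @ ap, index=ids)
            idx = model_based_index(y_focal.reindex(kept), proxy_gebv, K, kept)
            rows.append({"replicate": rep, "rate": rate,
                         "method": "model_based_index",
                         "accuracy": prediction_accuracy(
                             idx.iloc[vi].to_numpy(), y_val)})
    return CVReport(records=pd.DataFrame(rows), factors=("rate", "method"))
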
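"""Restricted-maximum-likelihood machinery shared by the mixed models.

Two workhorses live here:

* :func:`reml_kernel` — single-kernel REML (``V = sigma_u^2 K + sigma_e^2 I``)
  profiled over the variance ratio on the spectral decomposition of ``K``.
  This is the EMMA-style estimator behind RR-BLUP and GBLUP.
* :class:`VarianceComponentREML` — general multi-component REML
  (``V = sum_k sigma_k^2 Z_k Z_k' + sigma_e^2 I``) maximized directly over
  log variances, used for the phenotype adjustment models where crossed
  random effects (genotype, year, genotype-by-year) appear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["KernelREMLResult", "reml_kernel", "VarianceComponentREML", "VCResult"]


@dataclass
class KernelREMLResult:
    """REML estimates for a single-kernel mixed model."""

    sigma_u2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_u2
    beta: np.ndarray
    loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    resid: np.ndarray  # y - X beta, original coordinates

    @property
    def heritability(self) -> float:
        """sigma_u^2 / (sigma_u^2 + sigma_e^2); genomic h2 when K is a GRM."""
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)


def _neg_reml_loglik(log_delta: float, s: np.ndarray, ys: np.ndarray,
                     Xs: np.ndarray) -> float:
    """Profile REML negative log-likelihood over log(delta).

    ``s`` are eigenvalues of K, ``ys``/``Xs`` the rotated response/design.
    """
    delta = np.exp(log_delta)
    d = s + delta
    n, p = Xs.shape
    XtDX = (Xs.T / d) @ Xs
    XtDy = (Xs.T / d) @ ys
    try:
        beta = linalg.solve(XtDX, XtDy, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf
    r = ys - Xs @ beta
    rss = float(np.sum(r * r / d))
    if rss <= 0:
        return np.inf
    nf = n - p
    ll = -0.5 * (
        nf * np.log(2.0 * np.pi * rss / nf)
        + nf
        + np.sum(np.log(d))
        + np.log(max(linalg.det(XtDX), 1e-300))
    )
    return -ll


def reml_kernel(y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None,
                log_delta_bounds: tuple[float, float] = (-12.0, 12.0),
                n_grid: int = 40) -> KernelREMLResult:
    """Fit ``y = X beta + g + e`` with ``g ~ N(0, sigma_u^2 K)`` by REML.

    The variance ratio ``delta = sigma_e^2/sigma_u^2`` is profiled on the
    eigendecomposition of ``K``: a coarse grid locates the basin, Brent
    refines it (tolerance 1e-8 on log delta).

    Parameters
    ----------
    y : response vector, length n.
    K : n x n symmetric PSD kernel (GRM or ZZ').
    X : fixed-effect design; defaults to an intercept column.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if np.var(y) <= 0:
        raise ValueError("response has zero variance; nothing to fit")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n or K.shape != (n, n):
        raise ValueError("non-conformable y/X/K")

    s, U = linalg.eigh(K)
    s = np.clip(s, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([_neg_reml_loglik(g, s, ys, Xs) for g in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        _neg_reml_loglik, bounds=(a, b), args=(s, ys, Xs),
        method="bounded", options={"xatol": 1e-8})
    log_delta = float(res.x)
    delta = float(np.exp(log_delta))

    d = s + delta
    XtDX = (Xs.T / d) @ Xs
    beta = linalg.solve(XtDX, (Xs.T / d) @ ys, assume_a="pos")
    r = ys - Xs @ beta
    nf = n - X.shape[1]
    sigma_u2 = float(np.sum(r * r / d) / nf)
    sigma_e2 = sigma_u2 * delta
    return KernelREMLResult(
        sigma_u2=sigma_u2, sigma_e2=sigma_e2, delta=delta,
        beta=np.asarray(beta), loglik=-float(res.fun),
        eigvals=s, eigvecs=U, resid=y - X @ beta)


@dataclass
class VCResult:
    """REML estimates for a multi-component variance model."""

    variances: dict[str, float]
    sigma_e2: float
    beta: np.ndarray
    blups: dict[str, np.ndarray] = field(default_factory=dict)
    loglik: float = np.nan
    converged: bool = True


class VarianceComponentREML:
    """REML for ``y = X beta + sum_k Z_k b_k + e`` with independent b_k.

    Direct maximization of the restricted log-likelihood over log variance
    components (quasi-Newton, numerical gradient); suited to the small,
    possibly unbalanced designs of field-trial phenotype adjustment.
    """

    def __init__(self, y, X, random_designs: dict[str, np.ndarray]):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.names = list(random_designs)
        self.Z = {k: np.asarray(v, dtype=float) for k, v in random_designs.items()}
        self.G = {k: Z @ Z.T for k, Z in self.Z.items()}
        self.n = self.y.size

    def _neg_loglik(self, theta: np.ndarray):
        """Negative restricted log-likelihood and its gradient in log variances.

        Gradient uses d l / d s2_k = -0.5 [tr(P G_k) - y' P G_k P y] with
        P the REML projection matrix.
        """
        var = np.exp(theta)
        bad = (np.inf, np.zeros_like(theta))
        V = var[-1] * np.eye(self.n)
        for k, name in enumerate(self.names):
            V += var[k] * self.G[name]
        try:
            c, low = linalg.cho_factor(V, check_finite=False)
        except linalg.LinAlgError:
            return bad
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vi = linalg.cho_solve((c, low), np.eye(self.n), check_finite=False)
        Vi_X = Vi @ self.X
        XtViX = self.X.T @ Vi_X
        try:
            beta = linalg.solve(XtViX, Vi_X.T @ self.y, assume_a="pos")
            XtViX_inv_Xt = linalg.solve(XtViX, Vi_X.T, assume_a="pos")
        except linalg.LinAlgError:
            return bad
        r = self.y - self.X @ beta
        Vi_r = Vi @ r
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return bad
        nll = 0.5 * (logdetV + logdetX + float(r @ Vi_r))

        P = Vi - Vi_X @ XtViX_inv_Xt
        Py = P @ self.y
        grad = np.empty_like(theta)
        for k, name in enumerate(self.names):
            Gk = self.G[name]
            grad[k] = 0.5 * (np.sum(P * Gk) - float(Py @ (Gk @ Py))) * var[k]
        grad[-1] = 0.5 * (np.trace(P) - float(Py @ Py)) * var[-1]
        return nll, grad

    def fit(self, start: np.ndarray | None = None, maxiter: int = 200) -> VCResult:
        vy = np.var(self.y)
        k = len(self.names) + 1
        theta0 = np.log(np.full(k, max(vy, 1e-8) / k)) if start is None else np.log(start)
        res = optimize.minimize(
            self._neg_loglik, theta0, method="L-BFGS-B", jac=True,
            bounds=[(np.log(1e-10 * max(vy, 1e-8)), np.log(1e4 * max(vy, 1e-8)))] * k,
            options={"maxiter": maxiter, "ftol": 1e-11})
        var = np.exp(res.x)
        variances = {name: float(var[i]) for i, name in enumerate(self.names)}
        sigma_e2 = float(var[-1])

        V = sigma_e2 * np.eye(self.n)
        for i, name in enumerate(self.names):
            V += var[i] * self.G[name]
        c, low = linalg.cho_factor(V)
        Vi_X = linalg.cho_solve((c, low), self.X)
        beta = linalg.solve(self.X.T @ Vi_X, Vi_X.T @ self.y, assume_a="pos")
        r = self.y - self.X @ beta
        Vi_r = linalg.cho_solve((c, low), r)
        blups = {name: var[i] * (self.Z[name].T @ Vi_r)
                 for i, name in enumerate(self.names)}
        return VCResult(variances=variances, sigma_e2=sigma_e2,
                        beta=np.asarray(beta), blups=blups,
                        loglik=-float(res.fun), converged=bool(res.success))
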
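"""Dense REML engines.

Two fitters cover every model in the pipeline:

* :func:`reml_kernel` — single random kernel, y = Xb + u + e with
  u ~ N(0, K s2u), e ~ N(0, I s2e).  The restricted likelihood is
  profiled on the variance ratio delta = s2e/s2u after a one-time
  eigendecomposition of S K S (S the projection orthogonal to X), so
  each likelihood evaluation is O(n).  A low-rank path accepts an
  incidence matrix Z (K = Z Z') and solves a q x q eigenproblem
  instead.

* :func:`reml_general` — arbitrary sum of variance structures,
  V = s2e * (R(theta) + sum_j gamma_j Z_j Z_j'), with the overall scale
  s2e profiled out and the remaining log-ratios / correlations
  maximized by L-BFGS-B on dense Cholesky factorizations.  Trials and
  training sets are small enough (<= ~1000 observations) that dense
  algebra is the simplest correct choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh
from scipy.optimize import minimize, minimize_scalar

_LOG2PI = float(np.log(2.0 * np.pi))
_DELTA_LOG_BOUNDS = (-15.0, 15.0)


@dataclass
class KernelREMLResult:
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float
    beta: np.ndarray
    V: np.ndarray               # fitted covariance of y
    boundary: str | None = None  # "sigma2_u", "sigma2_e" or None


def _error_contrast_spectrum(y, X, K=None, Z=None):
    """Eigen-structure of S K S restricted to the complement of col(X)."""
    n, p = X.shape
    Q, _ = np.linalg.qr(X)

    def project(M):  # S @ M with S = I - QQ'
        return M - Q @ (Q.T @ M)

    Sy = project(y)
    if Z is not None:
        SZ = project(Z)
        G = SZ.T @ SZ  # q x q, same nonzero spectrum as S Z Z' S
        vals, vecs = eigh(G)
        keep = vals > max(1e-10, vals.max(initial=0.0) * 1e-12)
        xi = vals[keep]
        U = SZ @ (vecs[:, keep] / np.sqrt(xi))
        eta = U.T @ y
        total = float(Sy @ Sy)
        r0 = max(total - float(eta @ eta), 0.0)
        n0 = (n - p) - len(xi)
        return xi, eta, r0, max(n0, 0)
    A = project(project(np.asarray(K)).T)
    vals, vecs = eigh(A)
    order = np.argsort(vals)[::-1][: n - p]
    xi = np.clip(vals[order], 0.0, None)
    eta = vecs[:, order].T @ y
    return xi, eta, 0.0, 0


def reml_kernel(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    Z: np.ndarray | None = None,
    check_psd: bool = True,
) -> KernelREMLResult:
    """REML for a single-kernel mixed model via 1-D profile optimization."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n - p < 2:
        raise ValueError("too few error contrasts for REML")
    if K is not None and check_psd:
        Ks = np.asarray(K, dtype=float)
        if not np.allclose(Ks, Ks.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        if eigh(Ks, eigvals_only=True, subset_by_index=[0, 0])[0] < -1e-6:
            raise ValueError("kernel is not positive semi-definite")

    xi, eta, r0, n0 = _error_contrast_spectrum(y, X, K=K, Z=Z)
    m = n - p

    total_ss = float(eta @ eta) + r0
    if total_ss < 1e-12 * max(1.0, float(y @ y)):
        # constant response: both components at the zero boundary
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return KernelREMLResult(0.0, 0.0, np.nan, beta,
                                np.zeros((n, n)), boundary="sigma2_e")

    def negll(log_delta: float) -> float:
        d = np.exp(log_delta)
        denom = xi + d
        s = float((eta * eta / denom).sum()) + (r0 / d if n0 > 0 else 0.0)
        pen = float(np.log(denom).sum()) + (n0 * log_delta if n0 > 0 else 0.0)
        return 0.5 * (m * np.log(s) + pen)

    lo, hi = _DELTA_LOG_BOUNDS
    opt = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    log_delta = float(opt.x)
    # keep the better of interior optimum and the boundaries
    for cand in (lo, hi):
        if negll(cand) < negll(log_delta) - 1e-12:
            log_delta = cand
    delta = np.exp(log_delta)

    denom = xi + delta
    s = float((eta * eta / denom).sum()) + (r0 / delta if n0 > 0 else 0.0)
    sigma2_u = s / m
    sigma2_e = delta * sigma2_u
    loglik = -0.5 * (m * (_LOG2PI + 1.0 + np.log(sigma2_u))
                     + float(np.log(denom).sum()) + n0 * log_delta)

    boundary = None
    if log_delta >= hi - 1e-6:
        boundary = "sigma2_u"   # delta -> inf: genomic variance at zero
        sigma2_e = total_ss / m
        sigma2_u = 0.0
    elif log_delta <= lo + 1e-6:
        boundary = "sigma2_e"

    Kfull = np.asarray(K, dtype=float) if K is not None else Z @ Z.T
    V = sigma2_u * Kfull + sigma2_e * np.eye(n)
    beta = _gls_beta(y, X, V)
    return KernelREMLResult(sigma2_u, sigma2_e, float(loglik), beta, V, boundary)


def _gls_beta(y, X, V):
    n = len(y)
    Vr = V + 1e-10 * np.eye(n) * max(1.0, np.trace(V) / n)
    c = cho_factor(Vr, lower=True)
    Viy = cho_solve(c, y)
    ViX = cho_solve(c, X)
    XtViX = X.T @ ViX
    return np.linalg.solve(XtViX + 1e-12 * np.eye(X.shape[1]), X.T @ Viy)


# ---------------------------------------------------------------------------
# general multi-structure REML


@dataclass
class GeneralREMLResult:
    reml_loglik: float
    sigma2_e: float
    gammas: dict[str, float]        # variance ratios, absolute = gamma * s2e
    rhos: dict[str, float]
    beta: np.ndarray
    beta_cov: np.ndarray            # GLS covariance of the fixed effects
    n_var_params: int
    converged: bool = True
    boundary: list[str] = field(default_factory=list)

    def variance(self, name: str) -> float:
        return self.gammas[name] * self.sigma2_e


def reml_general(
    y: np.ndarray,
    X: np.ndarray,
    random_structures: dict[str, np.ndarray],
    residual_builder=None,
    rho_names: tuple[str, ...] = (),
    gamma_start: float = 0.5,
    rho_start: float = 0.2,
    rho_bound: float = 0.95,
    boundary_tol: float = 1e-5,
) -> GeneralREMLResult:
    """Profile-scale REML over variance ratios and AR1 correlations.

    ``random_structures`` maps names to Z_j Z_j' cross-product matrices
    (n x n); ``residual_builder(rhos: dict) -> R`` returns the residual
    correlation matrix (identity when None).  Ratios are optimized on a
    log scale, correlations through atanh, by L-BFGS-B.  The residual
    scale s2e is profiled analytically.  Ratios converging to the lower
    bound are reported as 0 (boundary).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    gnames = list(random_structures)
    struct = [np.asarray(random_structures[g], dtype=float) for g in gnames]
    k_gamma, k_rho = len(gnames), len(rho_names)
    atanh_bound = np.arctanh(rho_bound)

    def build_H(theta):
        gammas = np.exp(theta[:k_gamma])
        rhos = {r: float(np.tanh(theta[k_gamma + i]))
                for i, r in enumerate(rho_names)}
        H = residual_builder(rhos) if residual_builder else np.eye(n)
        H = np.array(H, dtype=float)
        for g, S in zip(gammas, struct):
            H += g * S
        return H, gammas, rhos

    def negll(theta):
        H, _, _ = build_H(theta)
        try:
            c = cholesky(H + 1e-8 * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            return 1e10
        logdet_H = 2.0 * float(np.log(np.diag(c)).sum())
        Hi_y = cho_solve((c, True), y)
        Hi_X = cho_solve((c, True), X)
        XtHiX = X.T @ Hi_X
        sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
        r = y - X @ beta
        rss = float(r @ (Hi_y - Hi_X @ beta))
        if rss <= 0:
            return 1e10
        s2 = rss / (n - p)
        return 0.5 * ((n - p) * (np.log(s2) + 1.0 + _LOG2PI)
                      + logdet_H + logdet_XtHiX)

    x0 = np.concatenate([
        np.full(k_gamma, np.log(gamma_start)),
        np.full(k_rho, np.arctanh(rho_start)),
    ])
    if len(x0) == 0:
        theta_opt, converged = x0, True
    else:
        bounds = ([(np.log(1e-6), np.log(1e6))] * k_gamma
                  + [(-atanh_bound, atanh_bound)] * k_rho)
        opt = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 200, "ftol": 1e-10})
        theta_opt, converged = opt.x, bool(opt.success)

    H, gammas_arr, rhos = build_H(theta_opt)
    c = cholesky(H + 1e-8 * np.eye(n), lower=True)
    Hi_y = cho_solve((c, True), y)
    Hi_X = cho_solve((c, True), X)
    XtHiX = X.T @ Hi_X
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    r = y - X @ beta
    s2 = float(r @ (Hi_y - Hi_X @ beta)) / (n - p)
    loglik = -negll(theta_opt)

    boundary = []
    gammas = {}
    for g, val in zip(gnames, gammas_arr):
        if val <= 1e-6 * (1 + boundary_tol):
            gammas[g] = 0.0
            boundary.append(g)
        else:
            gammas[g] = float(val)
    beta_cov = s2 * np.linalg.inv(XtHiX)

    return GeneralREMLResult(
        reml_loglik=float(loglik), sigma2_e=s2, gammas=gammas, rhos=rhos,
        beta=beta, beta_cov=beta_cov,
        n_var_params=1 + k_gamma + k_rho, converged=converged,
        boundary=boundary,
    )
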
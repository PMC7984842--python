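"""Random-intercept linear mixed models with Satterthwaite contrast tests.

The models used for protein- and module-level inference share one form:

    y = X beta + Z u + e,   u ~ N(0, sigma_g^2 I_q),   e ~ N(0, sigma^2 I_n)

with X the cell-means design over conditions and Z the indicator of a single
grouping factor (TMT mixture at the protein level, protein at the module
level). The covariance V = sigma^2 I + sigma_g^2 Z Z' is block diagonal, so
V^{-1} and log|V| have closed per-group forms and REML reduces to a 1-D
profiled optimization in the variance ratio lambda = sigma_g^2 / sigma^2.

A contrast l (sum-to-zero over condition means) is tested with
t = l'beta_hat / sqrt(l' C l), C = (X' V^{-1} X)^{-1}, with degrees of
freedom from the Satterthwaite moment approximation:
df = 2 g^2 / (grad_g' A grad_g), where g(theta) = l' C(theta) l and A is the
inverse observed REML information in theta = (sigma_g^2, sigma^2). When the
group variance is estimated at the zero boundary (or only one group exists)
the fit degrades to ordinary least squares and df is the residual df, the
exact value in that limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["MixedFit", "fit_random_intercept", "contrast"]

_LOG_LAMBDA_BOUNDS = (-14.0, 14.0)


@dataclass
class MixedFit:
    """REML fit of a random-intercept model (or its OLS degeneration)."""

    beta: np.ndarray
    vcov: np.ndarray  # covariance of beta at the REML variance estimates
    sigma2_g: float  # group (random intercept) variance
    sigma2: float  # residual variance
    n: int
    p: int
    ols_fallback: bool  # True when fit degraded to fixed-effects OLS
    _X: np.ndarray = None
    _groups: np.ndarray = None

    @property
    def residual_df(self) -> float:
        return float(self.n - self.p)


def _group_blocks(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sufficient statistics for the block-diagonal algebra."""
    blocks = []
    for g in np.unique(groups):
        m = groups == g
        Xg, yg = X[m], y[m]
        blocks.append((
            len(yg), Xg.T @ Xg, Xg.T @ yg, float(yg @ yg),
            Xg.sum(axis=0), float(yg.sum()),
        ))
    return blocks


def _gls_parts(blocks, lam: float):
    """X'V*^-1 X, X'V*^-1 y, y'V*^-1 y and log|V*| for V* = I + lam ZZ'."""
    p = blocks[0][1].shape[0]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for n_i, XtX, Xty, yty, xs, ys in blocks:
        c = lam / (1.0 + n_i * lam)
        XtVX += XtX - c * np.outer(xs, xs)
        XtVy += Xty - c * xs * ys
        ytVy += yty - c * ys * ys
        logdet += np.log1p(n_i * lam)
    return XtVX, XtVy, ytVy, logdet


def _profiled_m2reml(lam: float, blocks, n: int, p: int) -> float:
    XtVX, XtVy, ytVy, logdet = _gls_parts(blocks, lam)
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-300)
    return (n - p) * np.log(rss / (n - p)) + logdet + logdet_xvx


def _m2reml_theta(sg2: float, s2: float, blocks, n: int, p: int) -> float:
    """-2 REML log-likelihood (up to constant) at absolute variances."""
    if s2 <= 0 or sg2 < 0:
        return np.inf
    lam = sg2 / s2
    XtVX, XtVy, ytVy, logdet_vstar = _gls_parts(blocks, lam)
    sign, logdet_xvx = np.linalg.slogdet(XtVX / s2)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - beta @ XtVy, 1e-300)
    return n * np.log(s2) + logdet_vstar + logdet_xvx + rss / s2


def fit_random_intercept(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray
) -> MixedFit:
    """REML fit of y = X beta + (1|group) + e.

    With a single group, or a group variance estimated at the zero boundary,
    the fit falls back to OLS and is flagged via ``ols_fallback``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"model is saturated: n={n} <= p={p}")
    uniq = np.unique(groups)

    if len(uniq) < 2:
        return _ols_fit(y, X, groups)

    blocks = _group_blocks(X, y, groups)
    lo, hi = _LOG_LAMBDA_BOUNDS
    res = optimize.minimize_scalar(
        lambda t: _profiled_m2reml(np.exp(t), blocks, n, p),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    # compare against the boundary lambda = 0 (pure OLS)
    if _profiled_m2reml(0.0, blocks, n, p) <= res.fun or lam < 1e-6:
        return _ols_fit(y, X, groups)

    XtVX, XtVy, ytVy, _ = _gls_parts(blocks, lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - beta @ XtVy
    sigma2 = rss / (n - p)
    sigma2_g = lam * sigma2
    vcov = np.linalg.inv(XtVX) * sigma2
    return MixedFit(beta, vcov, float(sigma2_g), float(sigma2), n, p, False, X, groups)


def _ols_fit(y, X, groups) -> MixedFit:
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid / (n - p))
    vcov = np.linalg.inv(X.T @ X) * sigma2
    return MixedFit(beta, vcov, 0.0, sigma2, n, p, True, X, groups)


def satterthwaite_df(fit: MixedFit, l: np.ndarray, y: np.ndarray) -> float:
    if fit.ols_fallback:
        return fit.residual_df
    blocks = _group_blocks(fit._X, np.asarray(y, dtype=float), fit._groups)
    n, p = fit.n, fit.p
    theta = np.array([fit.sigma2_g, fit.sigma2])

    def g(th):
        lam = th[0] / th[1]
        XtVX, *_ = _gls_parts(blocks, lam)
        C = np.linalg.inv(XtVX) * th[1]
        return float(l @ C @ l)

    def nll(th):
        return 0.5 * _m2reml_theta(th[0], th[1], blocks, n, p)

    h = 1e-4 * np.maximum(theta, 1e-8)
    grad = np.zeros(2)
    H = np.zeros((2, 2))
    for i in range(2):
        e = np.zeros(2); e[i] = h[i]
        grad[i] = (g(theta + e) - g(theta - e)) / (2 * h[i])
        H[i, i] = (nll(theta + e) - 2 * nll(theta) + nll(theta - e)) / h[i] ** 2
    e0 = np.array([h[0], 0.0]); e1 = np.array([0.0, h[1]])
    H[0, 1] = H[1, 0] = (
        nll(theta + e0 + e1) - nll(theta + e0 - e1)
        - nll(theta - e0 + e1) + nll(theta - e0 - e1)
    ) / (4 * h[0] * h[1])
    try:
        A = np.linalg.inv(H)
        denom = float(grad @ A @ grad)
    except np.linalg.LinAlgError:
        denom = -1.0
    gval = g(theta)
    if denom <= 0 or not np.isfinite(denom):
        return fit.residual_df
    df = 2.0 * gval**2 / denom
    # the Satterthwaite df of a contrast cannot exceed the residual df by more
    # than numerical error and must be positive
    return float(np.clip(df, 1.0, fit.residual_df))


@dataclass
class ContrastOutcome:
    estimate: float
    se: float
    df: float
    t: float
    p: float


def contrast(fit: MixedFit, l: np.ndarray, y: np.ndarray | None = None) -> ContrastOutcome:
    """Test the sum-to-zero contrast l' beta = 0.

    ``y`` is required for the Satterthwaite df of a genuine mixed fit; in the
    OLS limit the residual df is exact and y may be omitted.
    """
    l = np.asarray(l, dtype=float)
    if abs(l.sum()) > 1e-12:
        raise ValueError("contrast coefficients must sum to zero")
    if not np.any(l != 0):
        raise ValueError("contrast is identically zero")
    est = float(l @ fit.beta)
    var = float(l @ fit.vcov @ l)
    if var <= 0:
        raise ValueError("contrast has zero estimated variance")
    se = float(np.sqrt(var))
    if fit.ols_fallback:
        df = fit.residual_df
    else:
        if y is None:
            raise ValueError("y is required for Satterthwaite df of a mixed fit")
        df = satterthwaite_df(fit, l, y)
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ContrastOutcome(est, se, df, t, max(p, np.finfo(float).tiny))
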
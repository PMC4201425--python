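"""Weighted binomial GLM/GLMM with logit link, fixed offset, and a spatial
block random intercept.

The regression model is

    logit P(y_i = 1) = x_i'β + offset_i + u_{b(i)},   u_b ~ N(0, σ²_α)

where rows are grid cells, prior weights down-weight pseudo-absences and
up-weight multi-report cells, the offset is the fixed-coefficient sampling
effort term, and u is a random intercept shared by all cells of one 2×2-cell
(4 km²) spatial block, absorbing residual spatial autocorrelation.

The plain GLM is fitted by iteratively reweighted least squares (IRLS).
The GLMM marginal likelihood integrates the random intercepts out with a
Laplace approximation: blocks are independent given β, so the integral
factorizes into one-dimensional block integrals, each approximated at its
conditional mode. The inner step is a penalized IRLS over (β, u) solved via
the Schur complement of the block-diagonal random-effect part; the outer
step is a bounded scalar search over log σ_α.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .design import ModelSpec
from .landscape import block_ids

_PCLIP = 1e-10
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
PIRLS_MAX_ITER = 200
SIGMA_BOUNDS = (1e-6, 10.0)  # on the sd scale
OUTER_TOL = 1e-6  # on log sigma


@dataclass
class FitResult:
    """Everything downstream scoring and prediction needs from one fit."""

    name: str
    params: pd.Series  # coefficients, index = ['intercept', ...predictors]
    bse: pd.Series
    loglik: float
    deviance: float
    sigma2_alpha: float
    n_obs: int
    k: int  # estimated parameters: fixed effects (+ variance component)
    fitted: np.ndarray  # conditional fitted probabilities, row order of design
    converged: bool
    flags: list[str] = dc_field(default_factory=list)
    u: dict[int, float] = dc_field(default_factory=dict)  # block -> mode
    centering: dict[str, float] = dc_field(default_factory=dict)
    offset_mean: float = 0.0
    offset_scale: float = 1.0
    linpred_fixed: np.ndarray | None = None  # x'β without offset/RE

    @property
    def predictors(self) -> list[str]:
        return [p for p in self.params.index if p != "intercept"]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "loglik": self.loglik,
            "deviance": self.deviance,
            "sigma2_alpha": self.sigma2_alpha,
            "n_obs": self.n_obs,
            "k": self.k,
            "converged": self.converged,
            "flags": list(self.flags),
            "centering": dict(self.centering),
            "offset_mean": self.offset_mean,
            "offset_scale": self.offset_scale,
        }


def _design_matrix(design: pd.DataFrame, spec: ModelSpec):
    names = ["intercept", *spec.predictors]
    X = np.column_stack(
        [np.ones(len(design))]
        + [design[p].to_numpy(dtype=float) for p in spec.predictors]
    )
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient design; collinear columns: {cols}")


def _bernoulli_loglik(y, mu, w) -> float:
    mu = np.clip(mu, _PCLIP, 1 - _PCLIP)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))


def _irls(X, y, w, offset):
    """Plain weighted IRLS. Returns (beta, info_matrix, converged, flags)."""
    n, p = X.shape
    beta = np.zeros(p)
    flags: list[str] = []
    converged = False
    A = None
    for _ in range(IRLS_MAX_ITER):
        eta = offset + X @ beta
        mu = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        v = mu * (1 - mu)
        W = w * v
        z = (eta - offset) + (y - mu) / v
        XtW = X.T * W
        A = XtW @ X
        try:
            new = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError:
            flags.append("singular_information")
            break
        step = np.max(np.abs(new - beta))
        beta = new
        if step < IRLS_TOL:
            converged = True
            break
    if not converged and "singular_information" not in flags:
        flags.append("not_converged")
    if np.max(np.abs(beta)) > 50:
        converged = False
        if "possible_separation" not in flags:
            flags.append("possible_separation")
    return beta, A, converged, flags


def fit_glm(
    design: pd.DataFrame,
    spec: ModelSpec,
    offset_scale: float = 1.0,
    response_col: str = "response",
    weight_col: str = "weight",
    offset_col: str = "offset",
) -> FitResult:
    """Fit a weighted binomial GLM with logit link and fixed offset.

    The log-likelihood is the prior-weighted Bernoulli log-likelihood; the
    deviance is −2× that value (the binary saturated model has zero
    log-likelihood). Perfect separation and degenerate responses are
    flagged on the returned result rather than raised.
    """
    X, names = _design_matrix(design, spec)
    _check_rank(X, names)
    y = design[response_col].to_numpy(dtype=float)
    w = design[weight_col].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("all prior weights must be positive")
    offset = offset_scale * design[offset_col].to_numpy(dtype=float)

    flags: list[str] = []
    if y.min() == y.max():
        flags.append("degenerate_response")

    beta, A, converged, irls_flags = _irls(X, y, w, offset)
    flags += [f for f in irls_flags if f not in flags]
    if "degenerate_response" in flags:
        converged = False
        if "possible_separation" not in flags:
            flags.append("possible_separation")

    eta = offset + X @ beta
    mu = expit(eta)
    ll = _bernoulli_loglik(y, mu, w)
    try:
        cov = np.linalg.inv(A)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    except (np.linalg.LinAlgError, TypeError):
        bse = np.full(len(names), np.nan)

    return FitResult(
        name=spec.name,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        loglik=ll,
        deviance=-2.0 * ll,
        sigma2_alpha=0.0,
        n_obs=len(y),
        k=len(names),
        fitted=mu,
        converged=converged,
        flags=flags,
        centering=dict(design.attrs.get("centering", {})),
        offset_mean=float(design.attrs.get("offset_mean", design[offset_col].mean())),
        offset_scale=offset_scale,
        linpred_fixed=X @ beta,
    )


def make_block_map(design: pd.DataFrame, block_size: int = 2, n_cols: int | None = None) -> np.ndarray:
    """Assign each design row to its square spatial super-block.

    Default blocks are 2×2 cells (4 km² on a 1-km² grid). ``n_cols`` defaults
    to one past the largest column index present.
    """
    rows = design["row"].to_numpy()
    cols = design["col"].to_numpy()
    if n_cols is None:
        n_cols = int(cols.max()) + 1
    return block_ids(rows, cols, block_size, n_cols)


def _pirls(X, y, w, offset, bidx, nb, sigma2, beta, u):
    """Penalized IRLS over (β, u) for fixed σ², via Schur complement.

    The random-effect normal equations are diagonal (one u per block), so
    β solves a p×p system after eliminating u. Returns the joint mode and
    the quantities needed for the Laplace correction and standard errors.
    """
    p = X.shape[1]
    converged = False
    S = None
    d = None
    for _ in range(PIRLS_MAX_ITER):
        eta = offset + X @ beta + u[bidx]
        mu = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        v = mu * (1 - mu)
        W = w * v
        z = (eta - offset) + (y - mu) / v
        d = np.bincount(bidx, weights=W, minlength=nb)
        r = np.bincount(bidx, weights=W * z, minlength=nb)
        C = np.zeros((nb, p))
        np.add.at(C, bidx, X * W[:, None])
        XtWX = X.T @ (X * W[:, None])
        XtWz = X.T @ (W * z)
        denom = d + 1.0 / sigma2
        S = XtWX - C.T @ (C / denom[:, None])
        rhs = XtWz - C.T @ (r / denom)
        beta_new = np.linalg.solve(S, rhs)
        u_new = (r - C @ beta_new) / denom
        step = max(np.max(np.abs(beta_new - beta)), np.max(np.abs(u_new - u)))
        beta, u = beta_new, u_new
        if step < IRLS_TOL:
            converged = True
            break
    return beta, u, S, d, converged


def _laplace_loglik(X, y, w, offset, bidx, nb, sigma2, beta, u):
    """Laplace-approximate marginal log-likelihood at the joint mode (β, û)."""
    eta = offset + X @ beta + u[bidx]
    mu = expit(eta)
    v = np.clip(mu, _PCLIP, 1 - _PCLIP)
    W = w * v * (1 - v)
    d = np.bincount(bidx, weights=W, minlength=nb)
    ll = _bernoulli_loglik(y, mu, w)
    ll -= float(np.sum(u**2) / (2 * sigma2))
    ll -= 0.5 * float(np.sum(np.log1p(sigma2 * d)))
    return ll


def marginal_loglik_quadrature(X, y, w, offset, bidx, nb, sigma2, beta, u_start=None, n_quad=21):
    """Adaptive Gauss–Hermite marginal log-likelihood (test-grade reference).

    Centers the quadrature at each block's conditional mode with curvature
    scaling; with one node this reduces to the Laplace approximation. Used
    to validate the Laplace route, not in the fitting path.
    """
    from numpy.polynomial.hermite import hermgauss

    sigma = np.sqrt(sigma2)
    nodes, weights = hermgauss(n_quad)
    if u_start is None:
        u_start = np.zeros(nb)
    # Find per-block modes by Newton steps on the penalized likelihood.
    u = u_start.copy()
    fixed = offset + X @ beta
    for _ in range(100):
        eta = fixed + u[bidx]
        mu = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        g = np.bincount(bidx, weights=w * (y - mu), minlength=nb) - u / sigma2
        h = np.bincount(bidx, weights=w * mu * (1 - mu), minlength=nb) + 1.0 / sigma2
        step = g / h
        u = u + step
        if np.max(np.abs(step)) < 1e-12:
            break
    scale = 1.0 / np.sqrt(h)  # curvature-based width per block
    total = 0.0
    for b in range(nb):
        rows = bidx == b
        pts = u[b] + np.sqrt(2.0) * scale[b] * nodes
        lb = np.empty(n_quad)
        for q, ub in enumerate(pts):
            eta = fixed[rows] + ub
            mu = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
            lb[q] = np.sum(
                w[rows] * (y[rows] * np.log(mu) + (1 - y[rows]) * np.log1p(-mu))
            ) - ub**2 / (2 * sigma2)
        m = lb.max()
        integral = np.sqrt(2.0) * scale[b] * np.sum(weights * np.exp(lb - m + nodes**2))
        total += m + np.log(integral) - 0.5 * np.log(2 * np.pi * sigma2)
    return float(total)


def fit_glmm(
    design: pd.DataFrame,
    spec: ModelSpec,
    blocks: np.ndarray | None = None,
    offset_scale: float = 1.0,
    block_size: int = 2,
    n_grid_cols: int | None = None,
    response_col: str = "response",
    weight_col: str = "weight",
    offset_col: str = "offset",
) -> FitResult:
    """Fit the binomial GLMM with a block random intercept (Laplace).

    ``blocks`` may be given explicitly; otherwise rows are mapped to
    ``block_size``×``block_size``-cell blocks from their grid indices.
    The variance component is profiled by a bounded search over log σ_α in
    [1e-6, 10]; at the lower bound the fit coincides with the GLM. ``k``
    counts the variance component as an estimated parameter.
    """
    X, names = _design_matrix(design, spec)
    _check_rank(X, names)
    y = design[response_col].to_numpy(dtype=float)
    w = design[weight_col].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("all prior weights must be positive")
    offset = offset_scale * design[offset_col].to_numpy(dtype=float)

    if blocks is None:
        blocks = make_block_map(design, block_size, n_grid_cols)
    labels, bidx = np.unique(np.asarray(blocks), return_inverse=True)
    nb = len(labels)
    flags: list[str] = []
    if nb == 1:
        warnings.warn("single spatial block: intercept and random effect are confounded")
        flags.append("single_block")
    if y.min() == y.max():
        flags.append("degenerate_response")
        flags.append("possible_separation")

    # Warm start from the GLM solution.
    beta0, _, _, glm_flags = _irls(X, y, w, offset)
    state = {"beta": beta0.copy(), "u": np.zeros(nb), "inner_failures": 0}

    def nll(log_sigma: float) -> float:
        sigma2 = np.exp(2.0 * log_sigma)
        beta, u, _, _, conv = _pirls(
            X, y, w, offset, bidx, nb, sigma2, state["beta"], state["u"]
        )
        if conv:
            state["beta"], state["u"] = beta, u
        else:
            state["inner_failures"] += 1
        return -_laplace_loglik(X, y, w, offset, bidx, nb, sigma2, beta, u)

    lo, hi = np.log(SIGMA_BOUNDS[0]), np.log(SIGMA_BOUNDS[1])
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": OUTER_TOL})
    sigma2 = float(np.exp(2.0 * res.x))
    beta, u, S, d, conv = _pirls(
        X, y, w, offset, bidx, nb, sigma2, state["beta"], state["u"]
    )
    ll = _laplace_loglik(X, y, w, offset, bidx, nb, sigma2, beta, u)

    converged = bool(res.success) and conv
    if not converged:
        flags.append("not_converged")
    if state["inner_failures"]:
        flags.append(f"inner_pirls_failures:{state['inner_failures']}")
    if np.max(np.abs(beta)) > 50:
        converged = False
        if "possible_separation" not in flags:
            flags.append("possible_separation")
    flags += [f for f in glm_flags if f == "possible_separation" and f not in flags]

    # At the lower variance bound the random effect is effectively absent.
    if res.x <= lo + 10 * OUTER_TOL:
        sigma2_report = 0.0
    else:
        sigma2_report = sigma2

    try:
        cov = np.linalg.inv(S)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(len(names), np.nan)

    eta = offset + X @ beta + u[bidx]
    mu = expit(eta)
    return FitResult(
        name=spec.name,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        loglik=ll,
        deviance=-2.0 * ll,
        sigma2_alpha=sigma2_report,
        n_obs=len(y),
        k=len(names) + 1,
        fitted=mu,
        converged=converged,
        flags=flags,
        u={int(lab): float(val) for lab, val in zip(labels, u)},
        centering=dict(design.attrs.get("centering", {})),
        offset_mean=float(design.attrs.get("offset_mean", design[offset_col].mean())),
        offset_scale=offset_scale,
        linpred_fixed=X @ beta,
    )


def predict_prob(
    fit: FitResult,
    new_rows: pd.DataFrame,
    include_random: bool = False,
    offset: np.ndarray | float | None = None,
    already_centered: bool = False,
    blocks: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted occurrence probability for new rows.

    ``new_rows`` must carry every predictor of the fitted model, on the raw
    scale unless ``already_centered``; the training centering constants are
    reapplied. ``offset`` defaults to the training-mean offset (a common
    reference effort). With ``include_random``, rows whose block has a
    conditional mode get it added; unknown blocks fall back to 0
    (population level).
    """
    missing = [p for p in fit.predictors if p not in new_rows.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {missing}")
    eta = np.full(len(new_rows), fit.params["intercept"], dtype=float)
    for p in fit.predictors:
        x = new_rows[p].to_numpy(dtype=float)
        if not already_centered:
            x = x - fit.centering.get(p, 0.0)
        eta += fit.params[p] * x
    if offset is None:
        offset = fit.offset_mean
    eta += fit.offset_scale * np.asarray(offset, dtype=float)
    if include_random and blocks is not None:
        eta += np.array([fit.u.get(int(b), 0.0) for b in blocks])
    return expit(eta)
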
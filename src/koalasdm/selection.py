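"""Model scoring, ranking and validation.

Information criteria (AICc, BIC) and their evidence weights, percentage of
deviance explained, Cohen's κ, stratified k-fold cross-validation, Moran's I
correlograms with Bonferroni correction, Nakagawa–Schielzeth marginal and
conditional R² for logit-link mixed models, and the aggregation of all of
these over repeated pseudo-absence draws into a single ranking table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from .design import ModelSpec
from .glmm import FitResult, fit_glm, fit_glmm, make_block_map, predict_prob

# ---------------------------------------------------------------------------
# Information criteria


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction,
    −2ℓ + 2k + 2k(k+1)/(n−k−1). Requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, −2ℓ + k·ln n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * np.log(n)


def info_weights(values) -> np.ndarray:
    """Evidence weights w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2), Δ_i = value − min.

    Computed after subtracting the minimum so no exponential overflows.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("criterion values must be finite and non-empty")
    delta = values - values.min()
    e = np.exp(-delta / 2.0)
    return e / e.sum()


def pct_deviance(fit: FitResult, null_fit: FitResult) -> float:
    """Percentage of deviance explained, 100·(1 − D/D_null)."""
    if null_fit.deviance == 0:
        raise ValueError("null deviance is zero")
    return 100.0 * (1.0 - fit.deviance / null_fit.deviance)


# ---------------------------------------------------------------------------
# Classification skill


def cohens_kappa(responses, probabilities, weights=None, threshold: float = 0.5) -> float:
    """Chance-corrected agreement between observed and predicted classes.

    Probabilities ≥ ``threshold`` classify as presence; the 2×2 confusion
    table is built with the prior weights, κ = (p_o − p_e)/(1 − p_e).
    Returns NaN (with a warning) when the marginals are degenerate
    (p_e = 1), where κ is undefined.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    y = np.asarray(responses, dtype=float)
    pred = (np.asarray(probabilities, dtype=float) >= threshold).astype(float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    total = w.sum()
    po = float(np.sum(w * (pred == y)) / total)
    p_obs1 = float(np.sum(w * y) / total)
    p_pred1 = float(np.sum(w * pred) / total)
    pe = p_obs1 * p_pred1 + (1 - p_obs1) * (1 - p_pred1)
    if abs(1.0 - pe) < 1e-12:
        warnings.warn("degenerate marginals: kappa undefined")
        return float("nan")
    return (po - pe) / (1.0 - pe)


def cross_validate(
    design: pd.DataFrame,
    spec: ModelSpec,
    n_folds: int = 10,
    seed: int = 0,
    use_random_effect: bool = True,
    offset_scale: float = 1.0,
    block_size: int = 2,
) -> tuple[float, float]:
    """Stratified k-fold prediction error for one model.

    Folds are stratified by response. Per fold the model is refitted on the
    remaining rows and the error is the weighted mean absolute difference
    between the held-out responses and their predicted probabilities
    (random-effect modes applied where the held-out block was seen in
    training). Returns ``(mean, sd)`` over folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(design) < n_folds:
        raise ValueError("fewer rows than folds")
    y = design["response"].to_numpy()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = design.iloc[train_idx]
        test = design.iloc[test_idx]
        if train["response"].nunique() < 2:
            warnings.warn("fold training set has a single response class")
        if use_random_effect:
            fit = fit_glmm(train, spec, offset_scale=offset_scale, block_size=block_size)
            blocks = make_block_map(test, block_size)
            p = predict_prob(
                fit,
                test,
                include_random=True,
                offset=test["offset"].to_numpy(),
                already_centered=True,
                blocks=blocks,
            )
        else:
            fit = fit_glm(train, spec, offset_scale=offset_scale)
            p = predict_prob(
                fit,
                test,
                offset=test["offset"].to_numpy(),
                already_centered=True,
            )
        w = test["weight"].to_numpy(dtype=float)
        errors.append(float(np.sum(w * np.abs(test["response"].to_numpy() - p)) / w.sum()))
    errors = np.asarray(errors)
    return float(errors.mean()), float(errors.std(ddof=1))


# ---------------------------------------------------------------------------
# Spatial autocorrelation


def _lag_pairs(rows: np.ndarray, cols: np.ndarray, lag: int):
    """Symmetric binary neighbor pairs at axis-aligned (rook) offset ``lag``.

    Cells i, j are lag-d neighbors when they sit exactly d cells apart
    along one grid axis: offsets (±d, 0) or (0, ±d).
    """
    index = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
    ii, jj = [], []
    for i, (r, c) in enumerate(zip(rows, cols)):
        for dr, dc in ((lag, 0), (0, lag)):
            j = index.get((r + dr, c + dc))
            if j is not None:
                ii.append(i)
                jj.append(j)
    # store both directions so w is symmetric
    return np.array(ii + jj, dtype=int), np.array(jj + ii, dtype=int)


def morans_i(values: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> tuple[float, float, float]:
    """Moran's I with expectation and randomization variance.

    ``ii, jj`` index the (symmetric, binary) neighbor pairs. Returns
    ``(I, E[I], Var[I])`` under the randomization null.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    z = x - x.mean()
    s2 = np.sum(z**2)
    if s2 == 0:
        raise ValueError("values have zero variance")
    s0 = float(len(ii))
    num = float(np.sum(z[ii] * z[jj]))
    I = (n / s0) * num / s2

    # randomization moments (binary symmetric weights)
    s1 = 2.0 * s0  # 0.5 * sum (w_ij + w_ji)^2 = 0.5 * (2^2 * s0/ ... ) for w in {0,1}
    deg = np.bincount(ii, minlength=n) + np.bincount(jj, minlength=n)
    s2w = float(np.sum(deg**2))
    b2 = n * np.sum(z**4) / s2**2
    e_i = -1.0 / (n - 1)
    num_var = n * ((n**2 - 3 * n + 3) * s1 - n * s2w + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2w + 6 * s0**2
    )
    den_var = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = num_var / den_var - e_i**2
    return float(I), float(e_i), float(var_i)


def morans_correlogram(
    values,
    rows,
    cols,
    n_lags: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moran's I correlogram over rook-ring lag classes with Bonferroni test.

    One row per lag 1..n_lags: the statistic, its two-sided normal-
    approximation p-value under the randomization null, and whether it is
    significant at the Bonferroni-corrected level ``alpha / n_lags``. Lags
    with no neighbor pairs yield NaN rows.
    """
    values = np.asarray(values, dtype=float)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if values.size < 8:
        raise ValueError("need at least 8 cells")
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if np.ptp(values) == 0:
        raise ValueError("values have zero variance")
    out = []
    for lag in range(1, n_lags + 1):
        ii, jj = _lag_pairs(rows, cols, lag)
        if len(ii) == 0:
            out.append((lag, np.nan, np.nan, False))
            continue
        I, e_i, var_i = morans_i(values, ii, jj)
        if var_i <= 0:
            out.append((lag, I, np.nan, False))
            continue
        zscore = (I - e_i) / np.sqrt(var_i)
        p = 2.0 * norm.sf(abs(zscore))
        out.append((lag, I, p, bool(p < alpha / n_lags)))
    return pd.DataFrame(out, columns=["lag", "I", "p", "significant"])


def pearson_residuals(fit: FitResult, design: pd.DataFrame) -> np.ndarray:
    """Weighted Pearson residuals, (y − μ)√w / √(μ(1−μ))."""
    y = design["response"].to_numpy(dtype=float)
    w = design["weight"].to_numpy(dtype=float)
    mu = np.clip(fit.fitted, 1e-10, 1 - 1e-10)
    return (y - mu) * np.sqrt(w) / np.sqrt(mu * (1 - mu))


# ---------------------------------------------------------------------------
# Mixed-model R²


def r2_nakagawa(fit: FitResult, design: pd.DataFrame | None = None) -> tuple[float, float]:
    """Marginal and conditional R² for a logit-link binomial (G)LMM.

    σ²_f is the variance of the fixed-effect linear predictor (offset
    excluded) over the fitted rows; the distribution-specific variance of
    the logit link is π²/3. Values are returned ×100, the percentage scale
    on which they are conventionally tabulated.
    """
    if fit.linpred_fixed is None:
        raise ValueError("fit carries no fixed-effect linear predictor")
    s2f = float(np.var(fit.linpred_fixed))
    s2a = fit.sigma2_alpha
    denom = s2f + s2a + np.pi**2 / 3.0
    return 100.0 * s2f / denom, 100.0 * (s2f + s2a) / denom


# ---------------------------------------------------------------------------
# Ranking over pseudo-absence iterations


@dataclass
class RankResult:
    """Aggregated ranking plus the per-iteration raw material."""

    table: pd.DataFrame
    per_iteration: pd.DataFrame
    fits: list[dict[str, FitResult]]
    weights: list[dict[str, float]]
    warnings: list[str] = dc_field(default_factory=list)


def rank_models(
    designs: list[pd.DataFrame],
    specs: list[ModelSpec],
    use_random_effect: bool = True,
    block_size: int = 2,
    offset_scale: float = 1.0,
    n_folds: int = 10,
    kappa_threshold: float = 0.5,
    cv_seed: int = 0,
) -> RankResult:
    """Fit every candidate on every pseudo-absence iteration and aggregate.

    Per iteration: each spec is fitted (GLMM by default), scored with AICc
    (→ evidence weights), BIC (→ weights), %De against the null fit, κ on
    the fitted probabilities, k-fold CV error (skipped when ``n_folds`` is
    0), and Nakagawa–Schielzeth R²; models are ranked by AICc. Across
    iterations the table reports the median rank (the headline ordering;
    ties broken by higher mean wAICc), mean weights, and mean ± SD of the
    per-iteration scores. Non-converged fits are dropped from that
    iteration with a warning.
    """
    if not designs:
        raise ValueError("need at least one design iteration")
    null_spec = next((s for s in specs if s.is_null), ModelSpec("null", ()))
    records = []
    all_fits: list[dict[str, FitResult]] = []
    all_weights: list[dict[str, float]] = []
    warn_log: list[str] = []

    for design in designs:
        it = int(design["iteration_id"].iloc[0]) if "iteration_id" in design else 0
        fits: dict[str, FitResult] = {}
        for spec in specs:
            if use_random_effect:
                fit = fit_glmm(design, spec, offset_scale=offset_scale, block_size=block_size)
            else:
                fit = fit_glm(design, spec, offset_scale=offset_scale)
            fits[spec.name] = fit
        null_fit = fits.get(null_spec.name)
        if null_fit is None or not null_fit.converged:
            if use_random_effect:
                null_fit = fit_glmm(design, null_spec, offset_scale=offset_scale, block_size=block_size)
            else:
                null_fit = fit_glm(design, null_spec, offset_scale=offset_scale)

        ok = {n: f for n, f in fits.items() if f.converged}
        dropped = sorted(set(fits) - set(ok))
        if dropped:
            msg = f"iteration {it}: non-converged fits excluded: {dropped}"
            warnings.warn(msg)
            warn_log.append(msg)
        if not ok:
            warn_log.append(f"iteration {it}: no converged fits; iteration skipped")
            continue

        names = list(ok)
        n = len(design)
        a_vals = np.array([aicc(ok[m].loglik, ok[m].k, n) for m in names])
        b_vals = np.array([bic(ok[m].loglik, ok[m].k, n) for m in names])
        w_aicc = info_weights(a_vals)
        w_bic = info_weights(b_vals)
        order = np.argsort(a_vals, kind="stable")
        ranks = np.empty(len(names), dtype=int)
        ranks[order] = np.arange(1, len(names) + 1)

        wmap = dict(zip(names, w_aicc))
        all_fits.append(fits)
        all_weights.append(wmap)

        for i, m in enumerate(names):
            fit = ok[m]
            kap = cohens_kappa(
                design["response"], fit.fitted, design["weight"], kappa_threshold
            )
            if n_folds >= 2:
                cv_mean, cv_sd = cross_validate(
                    design,
                    next(s for s in specs if s.name == m),
                    n_folds=n_folds,
                    seed=cv_seed + it,
                    use_random_effect=use_random_effect,
                    offset_scale=offset_scale,
                    block_size=block_size,
                )
            else:
                cv_mean, cv_sd = np.nan, np.nan
            r2m, r2c = r2_nakagawa(fit)
            records.append(
                {
                    "iteration": it,
                    "model": m,
                    "aicc": a_vals[i],
                    "bic": b_vals[i],
                    "waicc": w_aicc[i],
                    "wbic": w_bic[i],
                    "rank": ranks[i],
                    "pct_deviance": 0.0 if m == null_spec.name else pct_deviance(fit, null_fit),
                    "kappa": kap,
                    "cv_error": cv_mean,
                    "cv_error_sd": cv_sd,
                    "r2m": r2m,
                    "r2c": r2c,
                }
            )

    per_it = pd.DataFrame(records)
    if per_it.empty:
        raise RuntimeError("no iteration produced converged fits")
    agg = (
        per_it.groupby("model")
        .agg(
            median_rank=("rank", "median"),
            waicc_mean=("waicc", "mean"),
            wbic_mean=("wbic", "mean"),
            pct_deviance=("pct_deviance", "mean"),
            cv_error_mean=("cv_error", "mean"),
            cv_error_sd=("cv_error", "std"),
            kappa_mean=("kappa", "mean"),
            kappa_sd=("kappa", "std"),
            r2m=("r2m", "mean"),
            r2c=("r2c", "mean"),
            n_iterations=("iteration", "count"),
        )
        .reset_index()
    )
    agg = agg.sort_values(
        ["median_rank", "waicc_mean"], ascending=[True, False]
    ).reset_index(drop=True)
    return RankResult(agg, per_it, all_fits, all_weights, warn_log)
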
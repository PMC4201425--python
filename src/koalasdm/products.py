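"""Headline outputs: model-averaged effect sizes, habitat-suitability
rasters, maximum-density estimation, and suitability-scaled abundance.

The abundance chain converts a relative suitability surface s ∈ [0, 1]
into density via the linear rule D(s) = s·D_max/2 — density rises linearly
to half the maximum published density at perfect suitability — and sums
over 1-km² cells to a total population with a symmetric interval whose
relative half-width is the coefficient of variation SD/D_max of the
published maximum-density estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelSpec
from .glmm import FitResult, predict_prob
from .landscape import LandscapeGrid


# ---------------------------------------------------------------------------
# Effect sizes


def effect_sizes(
    fits_per_iteration: list[dict[str, FitResult]],
    weights_per_iteration: list[dict[str, float]],
) -> pd.DataFrame:
    """Model-averaged standardized effect sizes.

    Per iteration and predictor j: every converged model m containing j
    contributes its standardized coefficient β_j/SE_j times the fraction
    w_m / Σ_{m'∋j} w_{m'} of the evidence weight among models containing j;
    the contributions sum to the iteration's effect size, which is then
    averaged across iterations. Returns a table sorted by |effect|.
    """
    if not fits_per_iteration:
        raise ValueError("no fits supplied")
    predictors: list[str] = []
    for fits in fits_per_iteration:
        for fit in fits.values():
            for p in fit.predictors:
                if p not in predictors:
                    predictors.append(p)
    if not predictors:
        raise ValueError("no predictor appears in any candidate model")

    per_iter = {p: [] for p in predictors}
    for fits, wmap in zip(fits_per_iteration, weights_per_iteration):
        for p in predictors:
            contributions = []
            weights = []
            for name, w in wmap.items():
                fit = fits[name]
                if p in fit.predictors and fit.converged:
                    contributions.append(fit.params[p] / fit.bse[p])
                    weights.append(w)
            if weights:
                weights = np.asarray(weights)
                total = weights.sum()
                if total <= 0:
                    continue
                frac = weights / total
                per_iter[p].append(float(np.sum(frac * np.asarray(contributions))))
    rows = [
        {"predictor": p, "effect": float(np.mean(v)) if v else np.nan}
        for p, v in per_iter.items()
    ]
    out = pd.DataFrame(rows)
    return out.reindex(out["effect"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Suitability raster


@dataclass
class SuitabilityRaster:
    """Per-cell suitability in [0, 1] on the landscape grid."""

    values: np.ndarray  # shape (n_rows, n_cols)
    model: str
    n_iterations: int
    offset_reference: float

    def to_frame(self) -> pd.DataFrame:
        n_rows, n_cols = self.values.shape
        rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
        return pd.DataFrame(
            {"row": rows, "col": cols, "suitability": self.values.ravel()}
        )


def predict_suitability(
    spec: ModelSpec,
    fits: list[FitResult],
    grid: LandscapeGrid,
) -> SuitabilityRaster:
    """Iteration-averaged, population-level suitability surface.

    Each iteration's fit predicts at the population level: no random
    effect (levels are undefined off the training blocks) and the
    training-mean offset as the common reference effort. Cell-wise
    averaging across iterations yields the final surface.
    """
    if not fits:
        raise ValueError("no fits supplied")
    missing = [p for p in spec.predictors if p not in grid.predictors.columns]
    if missing:
        raise ValueError(f"target landscape lacks predictor(s): {missing}")
    acc = np.zeros(grid.n_cells)
    for fit in fits:
        acc += predict_prob(fit, grid.predictors, include_random=False)
    values = (acc / len(fits)).reshape(grid.n_rows, grid.n_cols)
    return SuitabilityRaster(
        values=values,
        model=spec.name,
        n_iterations=len(fits),
        offset_reference=float(np.mean([f.offset_mean for f in fits])),
    )


# ---------------------------------------------------------------------------
# Maximum density and abundance


@dataclass
class DmaxEstimate:
    """Summary of published maximum-density estimates (per ha and per km²)."""

    values_ha: np.ndarray
    excluded_ha: np.ndarray
    exclusion_threshold: float
    mean_ha: float
    sd_ha: float

    @property
    def mean_km2(self) -> float:
        return 100.0 * self.mean_ha

    @property
    def sd_km2(self) -> float:
        return 100.0 * self.sd_ha

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.sd_ha / self.mean_ha


def estimate_dmax(densities: pd.DataFrame, exclusion_threshold: float = 4.0) -> DmaxEstimate:
    """Mean and SD of published maximum densities after outlier exclusion.

    ``densities`` needs a ``density_ha`` column (animals per hectare).
    Values above ``exclusion_threshold`` (default 4 ha⁻¹, extreme
    irruptive densities) are excluded before taking the mean and sample SD.
    """
    if np.any(densities["density_ha"] < 0):
        raise ValueError("density values must be non-negative")
    vals = densities["density_ha"].to_numpy(dtype=float)
    keep = vals[vals <= exclusion_threshold]
    if keep.size == 0:
        raise ValueError("no density values remain after exclusion")
    sd = float(np.std(keep, ddof=1)) if keep.size > 1 else 0.0
    return DmaxEstimate(
        values_ha=keep,
        excluded_ha=vals[vals > exclusion_threshold],
        exclusion_threshold=exclusion_threshold,
        mean_ha=float(keep.mean()),
        sd_ha=sd,
    )


@dataclass
class AbundanceEstimate:
    """Total population scaled from suitability, with a symmetric interval."""

    total_area_km2: float
    sum_suitability: float
    mean: float
    ci_low: float
    ci_high: float
    density_low_km2: float
    density_high_km2: float
    dmax_mean_km2: float
    dmax_sd_km2: float

    def to_dict(self) -> dict:
        return {
            "area_km2": self.total_area_km2,
            "sum_suitability": self.sum_suitability,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "density_low_km2": self.density_low_km2,
            "density_high_km2": self.density_high_km2,
            "dmax_mean_km2": self.dmax_mean_km2,
            "dmax_sd_km2": self.dmax_sd_km2,
        }


def estimate_abundance(
    raster: SuitabilityRaster,
    dmax: DmaxEstimate,
    cell_area_km2: float = 1.0,
) -> AbundanceEstimate:
    """Scale suitability to density and sum to a total population.

    Per-cell density = suitability × D_max/2 (km⁻²); the mean population is
    the sum over cells times the cell area. The interval is
    mean × (1 ± SD/D_max) — symmetric about the mean with relative
    half-width equal to the coefficient of variation of the maximum-density
    estimates — floored at zero. The implied mean-density range divides the
    bounds by the total area.
    """
    if dmax.mean_km2 < 0:
        raise ValueError("negative maximum density")
    s = raster.values
    total_area = s.size * cell_area_km2
    sum_s = float(s.sum())
    mean_pop = sum_s * dmax.mean_km2 / 2.0 * cell_area_km2
    rel = dmax.sd_km2 / dmax.mean_km2 if dmax.mean_km2 > 0 else 0.0
    low = max(mean_pop * (1.0 - rel), 0.0)
    high = mean_pop * (1.0 + rel)
    return AbundanceEstimate(
        total_area_km2=total_area,
        sum_suitability=sum_s,
        mean=mean_pop,
        ci_low=low,
        ci_high=high,
        density_low_km2=low / total_area,
        density_high_km2=high / total_area,
        dmax_mean_km2=dmax.mean_km2,
        dmax_sd_km2=dmax.sd_km2,
    )


# ---------------------------------------------------------------------------
# Bias-component ablations


def ablation_design(
    design: pd.DataFrame,
    occurrence: pd.DataFrame,
    grid: LandscapeGrid,
    no_offset: bool = False,
    no_weights: bool = False,
    no_pseudoabsences: bool = False,
) -> pd.DataFrame:
    """Variant of a design table with bias corrections switched off.

    ``no_offset`` zeroes the effort offset; ``no_weights`` sets every prior
    weight to 1; ``no_pseudoabsences`` replaces the random pseudo-absence
    draw with *every* background cell of the training grid as a response-0
    row (the full-background design). Flags combine freely.
    """
    from .design import attach_predictors, center_predictors, compute_offset

    if no_pseudoabsences:
        observed_ids = set(occurrence["cell_id"])
        background = np.array(
            [c for c in range(grid.n_cells) if c not in observed_ids], dtype=int
        )
        pa_weight = design.loc[design["n_reports"] == 0, "weight"]
        weight = float(pa_weight.iloc[0]) if len(pa_weight) else 0.1
        bg = pd.DataFrame(
            {
                "cell_id": background,
                "row": background // grid.n_cols,
                "col": background % grid.n_cols,
                "response": 0,
                "weight": weight,
                "n_reports": 0,
            }
        )
        table = pd.concat([occurrence, bg], ignore_index=True)
        table = attach_predictors(table, grid)
        table["offset"] = compute_offset(table, grid)
        table, constants = center_predictors(table)
        table["iteration_id"] = 0
        table["seed"] = -1
        table.attrs["centering"] = constants
        table.attrs["offset_mean"] = float(table["offset"].mean())
    else:
        table = design.copy()
        table.attrs = dict(design.attrs)
    if no_weights:
        table["weight"] = 1.0
    if no_offset:
        table["offset"] = 0.0
        table.attrs["offset_mean"] = 0.0
    return table


def ablation_run(
    designs: list[pd.DataFrame],
    occurrence: pd.DataFrame,
    grid: LandscapeGrid,
    specs: list[ModelSpec],
    top_spec: ModelSpec,
    variants: dict[str, dict] | None = None,
    n_folds: int = 10,
    kappa_threshold: float = 0.5,
    offset_scale: float = 1.0,
    block_size: int = 2,
) -> pd.DataFrame:
    """Re-run the top-ranked model with bias corrections disabled in turn.

    For each variant the full candidate set is refitted on the modified
    design(s) so the top model's evidence weight is computed against the
    same competitors, and the table reports its wAICc, %De, CV error, κ,
    R²m/R²c, and the largest-magnitude model-averaged effect.
    """
    from .selection import rank_models

    if variants is None:
        variants = {
            "original": {},
            "no_offset": {"no_offset": True},
            "no_weights": {"no_weights": True},
            "no_pseudoabsences": {"no_pseudoabsences": True},
        }
    rows = []
    for label, flags in variants.items():
        mod_designs = [
            ablation_design(d, occurrence, grid, **flags) for d in designs
        ]
        if flags.get("no_pseudoabsences"):
            mod_designs = mod_designs[:1]  # deterministic: no random draw left
        result = rank_models(
            mod_designs,
            specs,
            n_folds=n_folds,
            kappa_threshold=kappa_threshold,
            offset_scale=offset_scale,
            block_size=block_size,
        )
        eff = effect_sizes(result.fits, result.weights)
        top_eff = eff.iloc[0]
        row = result.table.set_index("model").loc[top_spec.name]
        rows.append(
            {
                "variant": label,
                "waicc": row["waicc_mean"],
                "pct_deviance": row["pct_deviance"],
                "cv_error": row["cv_error_mean"],
                "kappa": row["kappa_mean"],
                "r2m": row["r2m"],
                "r2c": row["r2c"],
                "largest_effect_predictor": top_eff["predictor"],
                "largest_effect": top_eff["effect"],
            }
        )
    return pd.DataFrame(rows)
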
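"""Model-ready design tables: effort offsets, pseudo-absences, centering,
collinearity screening, and the fixed candidate model set.

The survey records where people looked as much as where koalas live. Two
bias corrections are assembled here: an *effort offset* — the inverse
distance from each cell to the nearest road, entering the linear predictor
with a fixed coefficient — and randomly placed, down-weighted
*pseudo-absences* that supply the background contrast that presence-heavy
data lack. Because the pseudo-absence draw is itself a source of model
uncertainty, the whole downstream analysis is repeated over many draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .landscape import PREDICTORS, LandscapeGrid

#: Predictor groups that candidate models are built from. Groups enter or
#: leave a model together (e.g. all three vegetation classes).
GROUPS: dict[str, tuple[str, ...]] = {
    "veg": ("koalaeuc", "othereuc", "otherveg"),
    "water": ("denswater", "dist2water"),
    "temp.range": ("temp_range",),
    "elevation": ("elevation",),
    "rain": ("rain",),
    "roads": ("sealed", "unsealed"),
    "koalaeuc": ("koalaeuc",),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named candidate model: a subset of predictor groups."""

    name: str
    groups: tuple[str, ...]

    @property
    def predictors(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.groups:
            for p in GROUPS[g]:
                if p not in seen:
                    seen.append(p)
        return tuple(seen)

    @property
    def is_null(self) -> bool:
        return len(self.groups) == 0


def build_model_set() -> list[ModelSpec]:
    """The fixed 15-model candidate set.

    Fourteen predictor combinations plus the intercept-only null model.
    *rain* and *elevation* never appear together: their rank correlation
    (ρ ≈ 0.9) makes their joint coefficients uninterpretable, so each model
    carries at most one of the pair.
    """
    combos: list[tuple[str, ...]] = [
        ("veg", "water", "temp.range", "elevation", "roads"),
        ("veg", "water", "temp.range", "rain", "roads"),
        ("veg", "water", "temp.range", "elevation"),
        ("veg", "temp.range", "rain"),
        ("veg", "water", "temp.range", "rain"),
        ("temp.range", "rain"),
        ("veg", "temp.range"),
        ("temp.range",),
        ("elevation",),
        ("veg", "water"),
        ("veg",),
        ("koalaeuc",),
        ("roads",),
        (),
        ("water",),
    ]
    specs = []
    for combo in combos:
        name = " + ".join(combo) if combo else "null"
        assert not ("rain" in combo and "elevation" in combo)
        specs.append(ModelSpec(name, combo))
    return specs


def compute_offset(
    cells: pd.DataFrame,
    grid: LandscapeGrid,
    min_distance: float = 1.0,
    distance_unit_m: float = 1000.0,
) -> np.ndarray:
    """Per-cell sampling-effort offset: 1 / distance to the nearest road.

    Distances are measured in metres from the cell centroid
    (``distance_unit_m`` converts landscape units to metres; the default
    grid unit is km). Distances below ``min_distance`` (default 1 m) are
    floored so cells crossed by a road get a finite offset of
    ``1/min_distance``.
    """
    if not min_distance > 0:
        raise ValueError("min_distance must be positive")
    if not grid.road_segments:
        raise ValueError("no road segments supplied")
    all_d = grid.road_distances() * distance_unit_m
    d = all_d[cells["cell_id"].to_numpy()]
    return 1.0 / np.maximum(d, min_distance)


def screen_collinearity(
    table: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Spearman correlation screen.

    Returns the full symmetric correlation matrix (unit diagonal) and a
    list of ``(a, b, rho)`` for pairs with ``|rho| >= threshold``. Constant
    columns yield undefined (NaN) correlations with a warning. The screen
    is advisory: the candidate set hard-codes the rain/elevation exclusion.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen collinearity")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    cols = list(table.columns)
    n = len(cols)
    mat = np.eye(n)
    for i in range(n):
        if table[cols[i]].nunique() <= 1:
            warnings.warn(f"predictor '{cols[i]}' is constant; correlations undefined")
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = table[cols[i]], table[cols[j]]
            if xi.nunique() <= 1 or xj.nunique() <= 1:
                rho = np.nan
            else:
                rho = spearmanr(xi, xj).statistic
            mat[i, j] = mat[j, i] = rho
    matrix = pd.DataFrame(mat, index=cols, columns=cols)
    flagged = [
        (cols[i], cols[j], float(mat[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(mat[i, j]) and abs(mat[i, j]) >= threshold
    ]
    return matrix, flagged


def sample_pseudoabsences(
    occurrence: pd.DataFrame,
    grid: LandscapeGrid,
    ratio: int = 10,
    pa_weight: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw background pseudo-absence cells.

    ``ratio`` cells per presence cell are drawn uniformly *without*
    replacement from grid cells not already in the occurrence table
    (observed absences included — they are already response-0 rows). Each
    draw is appended with response 0 and the down-weight ``pa_weight``
    (default 0.1), so 10 pseudo-absences per presence carry the same total
    weight as one presence.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if not pa_weight > 0:
        raise ValueError("pa_weight must be positive")
    if ratio == 0:
        return occurrence.copy()
    n_presence = int((occurrence["response"] == 1).sum())
    n_draw = ratio * n_presence
    occupied_ids = set(occurrence["cell_id"])
    pool = np.array(
        [c for c in range(grid.n_cells) if c not in occupied_ids], dtype=int
    )
    if pool.size < n_draw:
        raise ValueError(
            f"candidate pool ({pool.size}) smaller than requested "
            f"pseudo-absence count ({n_draw})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_draw, replace=False)
    pa = pd.DataFrame(
        {
            "cell_id": chosen,
            "row": chosen // grid.n_cols,
            "col": chosen % grid.n_cols,
            "response": 0,
            "weight": pa_weight,
            "n_reports": 0,
        }
    )
    return pd.concat([occurrence, pa], ignore_index=True)


def center_predictors(
    table: pd.DataFrame, predictors: list[str] | tuple[str, ...] = PREDICTORS
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Subtract the (unweighted) column mean from each predictor.

    Centering stabilizes the regression numerics and makes the intercept
    interpretable as the log-odds at average conditions; it changes no
    fitted probability. Returns the centered table and the centering
    constants for prediction-time reuse. Constant columns center to zero
    with a warning.
    """
    out = table.copy()
    constants: dict[str, float] = {}
    for name in predictors:
        col = out[name].to_numpy(dtype=float)
        m = float(col.mean())
        if np.ptp(col) == 0:
            warnings.warn(f"predictor '{name}' is constant; centered to all-zero")
        out[name] = col - m
        constants[name] = m
    return out, constants


def attach_predictors(cells: pd.DataFrame, grid: LandscapeGrid) -> pd.DataFrame:
    """Join raw predictor values from the landscape onto occurrence rows."""
    out = cells.copy()
    vals = grid.predictors.loc[out["cell_id"].to_numpy(), list(PREDICTORS)]
    for name in PREDICTORS:
        out[name] = vals[name].to_numpy()
    return out


def build_design(
    occurrence: pd.DataFrame,
    grid: LandscapeGrid,
    ratio: int = 10,
    pa_weight: float = 0.1,
    min_distance: float = 1.0,
    seed: int = 0,
    iteration_id: int = 0,
) -> pd.DataFrame:
    """Assemble one model-ready design table for a single pseudo-absence draw.

    Columns: cell identifiers, response, weight, effort offset, centered
    predictors, ``iteration_id`` and ``seed``. Centering constants are kept
    in ``DataFrame.attrs['centering']``; the mean offset (needed as the
    reference effort for out-of-sample prediction) in
    ``attrs['offset_mean']``.
    """
    table = sample_pseudoabsences(occurrence, grid, ratio, pa_weight, seed)
    table = attach_predictors(table, grid)
    table["offset"] = compute_offset(table, grid, min_distance)
    table, constants = center_predictors(table)
    table["iteration_id"] = iteration_id
    table["seed"] = seed
    table.attrs["centering"] = constants
    table.attrs["offset_mean"] = float(table["offset"].mean())
    return table


def build_design_iterations(
    occurrence: pd.DataFrame,
    grid: LandscapeGrid,
    n_iterations: int = 100,
    ratio: int = 10,
    pa_weight: float = 0.1,
    min_distance: float = 1.0,
    base_seed: int = 1,
) -> list[pd.DataFrame]:
    """One design table per pseudo-absence iteration (seeds base_seed + i).

    The observed-cell rows are identical across iterations; only the
    pseudo-absence complement varies.
    """
    return [
        build_design(
            occurrence,
            grid,
            ratio=ratio,
            pa_weight=pa_weight,
            min_distance=min_distance,
            seed=base_seed + i,
            iteration_id=i,
        )
        for i in range(n_iterations)
    ]
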
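"""Synthetic landscapes, occupancy surfaces, and road-biased sighting reports.

This module generates the test-bed for the whole pipeline: a rectangular
1-km² grid carrying the ten environmental and anthropogenic predictors used
in the koala habitat-suitability analysis, a sparse connected road network,
a "true" occupancy surface drawn from a logistic model with a spatial block
random intercept, and citizen-style sighting reports whose locations are
biased toward roads — the signature sampling artefact of opportunistic
wildlife surveys.

Everything is a pure function of its inputs and a seed, so downstream
stages (gridding, design construction, model fitting, abundance scaling)
are testable without any external data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import uniform_filter
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from scipy.special import expit
from scipy.stats import spearmanr
from shapely.geometry import LineString, MultiLineString

#: Canonical predictor names, in the order they are written to disk.
#: Areas are m² per 1-km² cell; densities are metres of feature per km²;
#: distances and elevation are metres; temp_range is °C; rain is mm.
PREDICTORS = (
    "koalaeuc",
    "othereuc",
    "otherveg",
    "denswater",
    "dist2water",
    "elevation",
    "sealed",
    "unsealed",
    "temp_range",
    "rain",
)

#: Activity labels a reporter can attach to a sighting.
ACTIVITIES = (
    "sleeping",
    "sitting",
    "eating",
    "climbing",
    "drinking",
    "walking",
    "dead",
    "other",
)

# Sighting-day activity mix: mostly low-activity animals, <10% feeding.
_ACTIVITY_PROBS = (0.37, 0.20, 0.08, 0.10, 0.02, 0.13, 0.02, 0.08)

CELL_AREA_M2 = 1_000_000.0  # 1 km² in m²


@dataclass(eq=False)
class LandscapeGrid:
    """A rectangular analysis grid with per-cell predictors and a road network.

    Coordinates are abstract Cartesian kilometres: cell (row, col) occupies
    the half-open square [col*cell_size, (col+1)*cell_size) ×
    [row*cell_size, (row+1)*cell_size) with the origin at the lower-left
    corner. ``predictors`` has one row per cell (row-major order, cell_id =
    row * n_cols + col) and one column per entry of :data:`PREDICTORS`,
    plus ``row`` and ``col`` indices.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    predictors: pd.DataFrame
    road_segments: list[LineString] = field(default_factory=list)
    _road_dist: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of all cell centroids, row-major order, in km."""
        rows = self.predictors["row"].to_numpy()
        cols = self.predictors["col"].to_numpy()
        x = (cols + 0.5) * self.cell_size
        y = (rows + 0.5) * self.cell_size
        return x, y

    def road_distances(self) -> np.ndarray:
        """Euclidean distance (km) from each cell centroid to the nearest road.

        Cached after the first call; the grid is treated as immutable.
        """
        if self._road_dist is None:
            if not self.road_segments:
                raise ValueError("landscape has no road segments")
            x, y = self.centroids()
            pts = shapely.points(np.column_stack([x, y]))
            network = MultiLineString(self.road_segments)
            self._road_dist = shapely.distance(pts, network)
        return self._road_dist

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) using half-open cell intervals."""
        col = np.floor(np.asarray(x) / self.cell_size).astype(int)
        row = np.floor(np.asarray(y) / self.cell_size).astype(int)
        return row, col


@dataclass(frozen=True)
class TrueModel:
    """Data-generating logistic model used to simulate occupancy.

    ``coefficients`` act on *centered* predictors (logit scale), so the
    intercept is the logit of occupancy probability at landscape-average
    conditions. ``re_sd`` is the standard deviation of a block-level random
    intercept, drawn once per square block of ``block_size`` cells per side.
    """

    coefficients: Mapping[str, float]
    intercept: float = 0.0
    re_sd: float = 0.0
    block_size: int = 2


def _smooth_standard_field(rng: np.random.Generator, shape, kernel: int = 3) -> np.ndarray:
    """Low-pass-filtered white noise, standardized to mean 0 / sd 1."""
    z = uniform_filter(rng.standard_normal(shape), size=kernel, mode="reflect")
    return (z - z.mean()) / z.std()


def _road_network(rng: np.random.Generator, width: float, height: float) -> list[LineString]:
    """Sparse connected network: minimum spanning tree over random waypoints."""
    n_nodes = int(np.clip(width * height / 60.0, 5, 40))
    pts = np.column_stack(
        [rng.uniform(0, width, n_nodes), rng.uniform(0, height, n_nodes)]
    )
    dist = squareform(pdist(pts))
    mst = minimum_spanning_tree(dist).tocoo()
    return [
        LineString([pts[i], pts[j]]) for i, j in zip(mst.row, mst.col)
    ]


def make_landscape(
    n_rows: int,
    n_cols: int,
    target_rain_elev_rho: float = 0.90,
    seed: int = 0,
    cell_size: float = 1.0,
    rho_tolerance: float = 0.05,
    max_calibration_iter: int = 50,
) -> LandscapeGrid:
    """Generate a seeded synthetic landscape.

    All predictor fields are spatially smooth (moving-average-filtered white
    noise, 3-cell kernel) and mutually independent, except *rain*, which is
    built as a monotone function of *elevation* plus smooth noise whose
    amplitude is calibrated by bisection so the realized Spearman rank
    correlation matches ``target_rain_elev_rho``. This reproduces the
    collinearity structure the analysis must cope with: one strongly
    correlated predictor pair, everything else essentially independent.

    Raises
    ------
    ValueError
        If dimensions are below 4×4, the target correlation is outside
        (0, 1), or bisection cannot reach the target within
        ``max_calibration_iter`` iterations.
    """
    if n_rows < 4 or n_cols < 4:
        raise ValueError("grid must be at least 4x4")
    if not 0.0 < target_rain_elev_rho < 1.0:
        raise ValueError("target_rain_elev_rho must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)

    # Independent smooth latent fields.
    z_veg = [_smooth_standard_field(rng, shape) for _ in range(3)]
    z_denswater = _smooth_standard_field(rng, shape)
    z_dist2water = _smooth_standard_field(rng, shape)
    z_elev = _smooth_standard_field(rng, shape)
    z_sealed = _smooth_standard_field(rng, shape)
    z_unsealed = _smooth_standard_field(rng, shape)
    z_temp = _smooth_standard_field(rng, shape)
    z_rain_noise = _smooth_standard_field(rng, shape)

    # Vegetation areas share each cell: softmax-style allocation against a
    # bare-ground class keeps each class within the cell area and their sum
    # below it.
    e = np.exp(np.stack(z_veg + [np.zeros(shape)]))
    frac = e / e.sum(axis=0)
    koalaeuc = frac[0] * CELL_AREA_M2
    othereuc = frac[1] * CELL_AREA_M2
    otherveg = frac[2] * CELL_AREA_M2

    elevation = np.clip(300.0 + 150.0 * z_elev, 0.0, None)

    # Calibrate rain = elevation signal + lam * noise so that the realized
    # Spearman rho hits the target. rho(lam) decreases monotonically in lam.
    flat_elev = z_elev.ravel()

    def realized_rho(lam: float) -> float:
        latent = flat_elev + lam * z_rain_noise.ravel()
        return float(spearmanr(flat_elev, latent).statistic)

    lo, hi = 0.0, 1.0
    it = 0
    while realized_rho(hi) > target_rain_elev_rho:
        hi *= 2.0
        it += 1
        if it > max_calibration_iter:
            raise ValueError("rain-elevation correlation target unattainable")
    for _ in range(max_calibration_iter):
        lam = 0.5 * (lo + hi)
        rho = realized_rho(lam)
        if abs(rho - target_rain_elev_rho) < 0.005:
            break
        if rho > target_rain_elev_rho:
            lo = lam
        else:
            hi = lam
    else:
        lam = 0.5 * (lo + hi)
        rho = realized_rho(lam)
    if abs(rho - target_rain_elev_rho) > rho_tolerance:
        raise ValueError(
            f"rain-elevation calibration failed: realized rho {rho:.3f}, "
            f"target {target_rain_elev_rho:.3f}"
        )
    rain_latent = z_elev + lam * z_rain_noise
    rain_latent = (rain_latent - rain_latent.mean()) / rain_latent.std()
    rain = np.clip(35.0 + 12.0 * rain_latent, 0.0, None)

    data = {
        "koalaeuc": koalaeuc,
        "othereuc": othereuc,
        "otherveg": otherveg,
        "denswater": 800.0 * np.exp(0.5 * z_denswater),
        "dist2water": 2000.0 * np.exp(0.6 * z_dist2water),
        "elevation": elevation,
        "sealed": 1500.0 * np.exp(0.6 * z_sealed),
        "unsealed": 700.0 * np.exp(0.6 * z_unsealed),
        "temp_range": 12.0 + 1.5 * z_temp,
        "rain": rain,
    }
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    table = pd.DataFrame({"row": rows, "col": cols})
    for name in PREDICTORS:
        table[name] = data[name].ravel()
    table.index.name = "cell_id"

    roads = _road_network(rng, n_cols * cell_size, n_rows * cell_size)
    return LandscapeGrid(n_rows, n_cols, cell_size, table, roads)


def block_ids(rows: np.ndarray, cols: np.ndarray, block_size: int, n_cols: int) -> np.ndarray:
    """Label each cell with its square super-block (block_size cells per side)."""
    n_block_cols = -(-n_cols // block_size)
    return (np.asarray(rows) // block_size) * n_block_cols + np.asarray(cols) // block_size


def simulate_occupancy(
    grid: LandscapeGrid, truth: TrueModel, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a true occupancy surface from the generating model.

    Returns ``(probability, presence)``, both 1-D arrays aligned with
    ``grid.predictors`` (row-major). Probability is the inverse-logit of
    intercept + Σ β·(predictor − landscape mean) + block random intercept;
    presence is a Bernoulli draw per cell.
    """
    unknown = set(truth.coefficients) - set(PREDICTORS)
    if unknown:
        raise ValueError(f"unknown predictor(s) in TrueModel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    eta = np.full(grid.n_cells, truth.intercept, dtype=float)
    for name, beta in truth.coefficients.items():
        x = grid.predictors[name].to_numpy()
        eta += beta * (x - x.mean())
    if truth.re_sd > 0:
        blocks = block_ids(
            grid.predictors["row"].to_numpy(),
            grid.predictors["col"].to_numpy(),
            truth.block_size,
            grid.n_cols,
        )
        n_blocks = blocks.max() + 1
        u = rng.normal(0.0, truth.re_sd, n_blocks)
        eta += u[blocks]
    prob = expit(eta)
    presence = rng.random(grid.n_cells) < prob
    return prob, presence.astype(int)


def simulate_reports(
    presence_field: np.ndarray,
    grid: LandscapeGrid,
    detect_at_road: float = 1.0,
    distance_decay: float = 0.5,
    n_reports: int = 1359,
    absence_fraction: float = 115 / 1359,
    absence_reports_per_site: float = 3.5,
    seed: int = 0,
    survey_date: str = "2012-11-28",
    coord_precision: float = 0.01,
) -> pd.DataFrame:
    """Simulate road-biased citizen sighting reports.

    Report locations are drawn cell-wise with probability proportional to
    ``detect_at_road * exp(-d / distance_decay)`` where ``d`` is the cell's
    distance to the nearest road — opportunistic observers rarely stray far
    from the transport network. Presence reports come only from occupied
    cells; a small fraction (default 115/1359, the prevalence bias typical
    of sighting-centric surveys) are absence reports from unoccupied cells.
    Absence reports cluster on a limited number of distinct search sites
    (``absence_reports_per_site`` reports per site on average), mirroring
    how non-sightings concentrate at a handful of well-visited locations.
    ``distance_decay=numpy.inf`` disables the road bias (uniform sampling).

    Coordinates are jittered uniformly within the cell and then rounded to
    ``coord_precision`` landscape units, emulating the coarse 0.01° fix of
    web-reported locations. Timestamps fall on ``survey_date`` between
    06:00 and 20:00.
    """
    if not 0 < detect_at_road <= 1:
        raise ValueError("detect_at_road must lie in (0, 1]")
    if not distance_decay > 0:
        raise ValueError("distance_decay must be positive")
    if not 0 <= absence_fraction < 0.5:
        raise ValueError("absence_fraction must lie in [0, 0.5)")
    presence_field = np.asarray(presence_field).ravel()
    occupied = np.flatnonzero(presence_field == 1)
    if occupied.size == 0:
        raise ValueError("no occupied cells to report from")

    rng = np.random.default_rng(seed)
    d = grid.road_distances()
    if np.isinf(distance_decay):
        w = np.full(grid.n_cells, detect_at_road)
    else:
        w = detect_at_road * np.exp(-d / distance_decay)

    n_absence = rng.binomial(n_reports, absence_fraction)
    n_presence = n_reports - n_absence

    def draw_cells(pool: np.ndarray, k: int) -> np.ndarray:
        p = w[pool]
        total = p.sum()
        p = np.full(pool.size, 1.0 / pool.size) if total <= 0 else p / total
        return rng.choice(pool, size=k, replace=True, p=p)

    unoccupied = np.flatnonzero(presence_field == 0)
    absence_pool = unoccupied if unoccupied.size else np.arange(grid.n_cells)
    if n_absence > 0 and absence_reports_per_site > 1:
        # Concentrate absences on a few well-visited search sites.
        n_sites = min(
            absence_pool.size, max(1, round(n_absence / absence_reports_per_site))
        )
        p = w[absence_pool]
        p = p / p.sum() if p.sum() > 0 else None
        absence_pool = rng.choice(absence_pool, size=n_sites, replace=False, p=p)

    cells = np.concatenate(
        [draw_cells(occupied, n_presence), draw_cells(absence_pool, n_absence)]
    )
    response = np.concatenate(
        [np.ones(n_presence, dtype=int), np.zeros(n_absence, dtype=int)]
    )

    rows = grid.predictors["row"].to_numpy()[cells]
    cols = grid.predictors["col"].to_numpy()[cells]
    x = (cols + rng.random(cells.size)) * grid.cell_size
    y = (rows + rng.random(cells.size)) * grid.cell_size
    x = np.round(x / coord_precision) * coord_precision
    y = np.round(y / coord_precision) * coord_precision
    # rounding must not push a report off the half-open grid
    x = np.clip(x, 0.0, grid.n_cols * grid.cell_size - coord_precision)
    y = np.clip(y, 0.0, grid.n_rows * grid.cell_size - coord_precision)

    minutes = rng.integers(6 * 60, 20 * 60, cells.size)
    timestamps = pd.to_datetime(survey_date) + pd.to_timedelta(minutes, unit="m")
    activity = np.where(
        response == 1,
        rng.choice(ACTIVITIES, size=cells.size, p=_ACTIVITY_PROBS),
        "other",
    )

    reports = pd.DataFrame(
        {
            "lon": x,
            "lat": y,
            "timestamp": timestamps,
            "response": response,
            "activity": activity,
        }
    )
    return reports.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Serialization


def write_landscape(grid: LandscapeGrid, csv_path, roads_path) -> None:
    """Write cells as CSV and the road network as a GeoJSON LineString file."""
    grid.predictors.to_csv(csv_path, index=True)
    features = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": json.loads(shapely.to_geojson(seg)),
        }
        for seg in grid.road_segments
    ]
    with open(roads_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_landscape(csv_path, roads_path, cell_size: float = 1.0) -> LandscapeGrid:
    table = pd.read_csv(csv_path, index_col="cell_id")
    n_rows = int(table["row"].max()) + 1
    n_cols = int(table["col"].max()) + 1
    if len(table) != n_rows * n_cols:
        warnings.warn("landscape CSV does not cover a complete rectangle")
    with open(roads_path) as fh:
        geo = json.load(fh)
    roads = [
        shapely.from_geojson(json.dumps(feat["geometry"]))
        for feat in geo["features"]
    ]
    return LandscapeGrid(n_rows, n_cols, cell_size, table, roads)
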
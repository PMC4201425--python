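import numpy as np
import pandas as pd
import pytest

import koalasdm as k


@pytest.fixture(scope="session")
def grid():
    """Small landscape shared across tests (30x30 km, seeded)."""
    return k.make_landscape(30, 30, 0.90, seed=11)


@pytest.fixture(scope="session")
def truth():
    return k.DEFAULT_TRUTH


@pytest.fixture(scope="session")
def occupancy(grid, truth):
    prob, presence = k.simulate_occupancy(grid, truth, seed=12)
    return prob, presence


@pytest.fixture(scope="session")
def reports(grid, occupancy):
    _, presence = occupancy
    return k.simulate_reports(presence, grid, n_reports=250, seed=13)


@pytest.fixture(scope="session")
def occurrence(grid, reports):
    cleaned, _ = k.clean_reports(reports)
    occ, _ = k.rasterize_reports(cleaned, grid)
    return occ


@pytest.fixture(scope="session")
def design(grid, occurrence):
    return k.build_design(occurrence, grid, ratio=5, seed=17)


@pytest.fixture(scope="session")
def specs():
    return k.build_model_set()


def straight_road_grid(n_rows=8, n_cols=8, cell_size=1.0):
    """Minimal grid with a single road along the bottom edge (y = 0)."""
    from shapely.geometry import LineString

    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    table = pd.DataFrame({"row": rows, "col": cols})
    rng = np.random.default_rng(0)
    for name in k.PREDICTORS:
        table[name] = rng.random(n_rows * n_cols)
    table.index.name = "cell_id"
    road = LineString([(0.0, 0.0), (n_cols * cell_size, 0.0)])
    return k.LandscapeGrid(n_rows, n_cols, cell_size, table, [road])


@pytest.fixture()
def road_grid():
    return straight_road_grid()


def simulated_design(
    n=1000,
    beta=(0.5, -1.0),
    intercept=0.2,
    seed=0,
    re_sd=0.0,
    n_blocks=1,
    weights=None,
    offset_sd=0.0,
):
    """Bernoulli regression data with known coefficients for recovery tests."""
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.normal(size=(n, p))
    offset = rng.normal(scale=offset_sd, size=n) if offset_sd else np.zeros(n)
    blocks = rng.integers(0, n_blocks, n)
    u = rng.normal(0, re_sd, n_blocks) if re_sd else np.zeros(n_blocks)
    eta = intercept + X @ np.asarray(beta) + offset + u[blocks]
    y = (rng.random(n) < expit(eta)).astype(int)
    d = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
    d["response"] = y
    d["weight"] = 1.0 if weights is None else weights
    d["offset"] = offset
    return d, blocks


class FreeSpec:
    """Ad-hoc model spec over arbitrary column names (bypasses GROUPS)."""

    def __init__(self, name, predictors):
        self.name = name
        self._predictors = tuple(predictors)

    @property
    def predictors(self):
        return self._predictors

    @property
    def is_null(self):
        return len(self._predictors) == 0
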
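"""Report cleaning and rasterization onto the 1-km² analysis grid.

Citizen reports arrive as point records; the analysis works on grid cells.
Cleaning removes duplicates and malformed records with an explicit
rejection log; rasterization collapses reports to one row per occupied
cell, recording a presence/absence response and a report-count weight —
cells with several reports carry proportionally more weight in the
downstream weighted regressions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .landscape import LandscapeGrid

REPORT_COLUMNS = ("lon", "lat", "timestamp", "response", "activity")


def clean_reports(reports: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate and de-duplicate raw sighting reports.

    Returns ``(kept, rejection_log)``. The log has one row per rejected
    record with columns ``index`` (position in the input) and ``reason``
    (``invalid_coordinate``, ``invalid_response`` or ``duplicate``).
    Exact duplicates — same rounded coordinates, timestamp and response —
    collapse to their first occurrence.
    """
    if len(reports) == 0:
        warnings.warn("clean_reports received an empty report table")
        return reports.copy(), pd.DataFrame(columns=["index", "reason"])

    log_entries: list[tuple[int, str]] = []
    lon = pd.to_numeric(reports["lon"], errors="coerce")
    lat = pd.to_numeric(reports["lat"], errors="coerce")
    bad_coord = ~(np.isfinite(lon) & np.isfinite(lat))
    bad_resp = ~reports["response"].isin([0, 1])

    for idx in reports.index[bad_coord]:
        log_entries.append((idx, "invalid_coordinate"))
    for idx in reports.index[~bad_coord & bad_resp]:
        log_entries.append((idx, "invalid_response"))

    kept = reports[~bad_coord & ~bad_resp].copy()
    dup = kept.duplicated(subset=["lon", "lat", "timestamp", "response"], keep="first")
    for idx in kept.index[dup]:
        log_entries.append((idx, "duplicate"))
    kept = kept[~dup]

    log = pd.DataFrame(log_entries, columns=["index", "reason"])
    return kept.reset_index(drop=True), log


def rasterize_reports(
    reports: pd.DataFrame, grid: LandscapeGrid
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse cleaned reports to per-cell occurrence rows.

    One output row per grid cell containing at least one report, with
    ``response`` = 1 if *any* report in the cell is a presence (a single
    sighting is evidence of occupancy regardless of co-located absences),
    ``weight`` = number of reports in the cell, and ``n_reports`` likewise.
    Cell membership uses half-open intervals, so a point on a shared edge
    belongs to exactly one cell. Reports outside the grid are dropped and
    logged.

    Returns ``(occurrence_table, drop_log)``.
    """
    row, col = grid.cell_index(reports["lon"].to_numpy(), reports["lat"].to_numpy())
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    drop_log = pd.DataFrame(
        {"index": reports.index[~inside], "reason": "outside_grid"}
    )

    kept = reports[inside]
    cell_id = row[inside] * grid.n_cols + col[inside]
    agg = pd.DataFrame(
        {"cell_id": cell_id, "response": kept["response"].to_numpy()}
    ).groupby("cell_id")["response"]

    occ = pd.DataFrame(
        {
            "response": (agg.max()).astype(int),  # presence dominates
            "n_reports": agg.size().astype(int),
        }
    )
    occ["weight"] = occ["n_reports"].astype(float)
    occ = occ.reset_index()
    occ["row"] = occ["cell_id"] // grid.n_cols
    occ["col"] = occ["cell_id"] % grid.n_cols
    return occ[["cell_id", "row", "col", "response", "weight", "n_reports"]], drop_log
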
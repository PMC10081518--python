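"""Alignment of all inputs onto the modeling grid at hourly resolution.

Three steps: sub-hourly satellite products are aggregated to cell-hours
(AOD by the mean of valid retrievals, detection masks by the any-rule);
meteorology points are joined to grid cells by an injective greedy
nearest-neighbor match (no two points share a cell); ground observations
are deduplicated so each cell-hour carries a single value, with regulatory
measurements superseding low-cost ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import AQS, PURPLEAIR
from .geo import pairwise_haversine_m

DEFAULT_PA_WEIGHT = 0.15

MET_FIELDS = ["temperature_2m", "pressure", "u10", "v10", "pblh", "rh"]


class FusionError(RuntimeError):
    pass


def aggregate_satellite_hourly(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse sub-hourly satellite records to one row per cell-hour.

    AOD is the mean of valid retrievals within the hour; each binary mask is
    1 if any valid sub-hourly record flagged it. Cell-hours with zero valid
    records are null. Permutation-invariant in the record order.
    """
    cols = ["cell_id", "hour", "aod", "smoke_mask", "dust_mask", "aerosol_mask"]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "cell_id": records["cell_id"],
            "hour": records["hour"],
            "aod": records["aod"].where(records["aod_valid"].astype(bool)),
            "smoke_mask": records["smoke"].astype(float).where(records["mask_valid"].astype(bool)),
            "dust_mask": records["dust"].astype(float).where(records["mask_valid"].astype(bool)),
            "aerosol_mask": records["aerosol"].astype(float).where(records["mask_valid"].astype(bool)),
        }
    )
    g = df.groupby(["cell_id", "hour"], sort=True)
    out = g.agg(
        aod=("aod", "mean"),
        smoke_mask=("smoke_mask", "max"),
        dust_mask=("dust_mask", "max"),
        aerosol_mask=("aerosol_mask", "max"),
    ).reset_index()
    return out[cols]


@dataclass
class MetAssignment:
    """Injective met-point → grid-cell assignment.

    ``table`` has one row per grid cell: cell_id, point_id, distance_m,
    inherited. Cells that received no point directly inherit the point of
    their nearest assigned cell (``inherited=True``).
    """

    table: pd.DataFrame
    n_direct: int


def join_met_to_grid(met_points: pd.DataFrame, grid: pd.DataFrame) -> MetAssignment:
    """Greedy injective nearest-neighbor assignment of met points to cells.

    Candidate (point, cell) pairs are visited in increasing great-circle
    distance (ties by point_id then cell_id lexical order); a pair is taken
    whenever both members are still free, so each cell receives at most one
    point and every point is used exactly once when cells outnumber points.
    """
    if len(met_points) == 0:
        raise FusionError("zero met points")
    P, C = len(met_points), len(grid)
    d = pairwise_haversine_m(met_points["lon"], met_points["lat"], grid["lon"], grid["lat"])
    p_rank = np.argsort(np.argsort(met_points["point_id"].astype(str).to_numpy(), kind="stable"))
    c_rank = np.argsort(np.argsort(grid["cell_id"].to_numpy(), kind="stable"))
    flat = d.ravel()
    p_idx_all, c_idx_all = np.divmod(np.arange(P * C), C)
    order = np.lexsort((c_rank[c_idx_all], p_rank[p_idx_all], flat))
    point_used = np.zeros(P, dtype=bool)
    cell_point = np.full(C, -1, dtype=np.int64)
    cell_dist = np.full(C, np.nan)
    n_assigned, target = 0, min(P, C)
    for k in order:
        pi, ci = p_idx_all[k], c_idx_all[k]
        if point_used[pi] or cell_point[ci] >= 0:
            continue
        point_used[pi] = True
        cell_point[ci] = pi
        cell_dist[ci] = flat[k]
        n_assigned += 1
        if n_assigned == target:
            break

    inherited = cell_point < 0
    if inherited.any():
        glon = grid["lon"].to_numpy()
        glat = grid["lat"].to_numpy()
        dd = pairwise_haversine_m(glon[inherited], glat[inherited], glon[~inherited], glat[~inherited])
        donor = np.flatnonzero(~inherited)[np.argmin(dd, axis=1)]
        cell_point[inherited] = cell_point[donor]

    point_ids = met_points["point_id"].to_numpy()
    table = pd.DataFrame(
        {
            "cell_id": grid["cell_id"].to_numpy(),
            "point_id": point_ids[cell_point],
            "distance_m": cell_dist,
            "inherited": inherited,
        }
    )
    return MetAssignment(table=table, n_direct=int(n_assigned))


def met_to_cell_hours(assignment: MetAssignment, met_values: pd.DataFrame) -> pd.DataFrame:
    """Expand the assignment to per-cell-hour meteorology rows."""
    return assignment.table[["cell_id", "point_id"]].merge(met_values, on="point_id")[
        ["cell_id", "hour"] + MET_FIELDS
    ]


def dedup_ground(
    observations: pd.DataFrame, pa_weight: float = DEFAULT_PA_WEIGHT
) -> pd.DataFrame:
    """One ground value per cell-hour.

    If a cell-hour holds any regulatory (AQS) measurement, the low-cost
    values there are discarded and the AQS values averaged (weight 1.0);
    otherwise low-cost values are averaged with weight ``pa_weight``. Each
    row also carries a representative ``station_id`` — the lexically first
    station ever contributing to the cell on the winning network — so that
    spatial cross-validation can move all of a cell's rows as one monitor.
    """
    cols = ["cell_id", "hour", "pm25", "network", "weight", "station_id", "lon", "lat"]
    if len(observations) == 0:
        return pd.DataFrame(columns=cols)
    aqs = observations[observations["network"] == AQS]
    pa = observations[observations["network"] == PURPLEAIR]

    def _collapse(df, network, weight):
        if len(df) == 0:
            return pd.DataFrame(columns=cols)
        rep = df.groupby("cell_id")["station_id"].min().rename("station_id")
        g = df.groupby(["cell_id", "hour"], sort=True).agg(
            pm25=("pm25", "mean"), lon=("lon", "mean"), lat=("lat", "mean")
        ).reset_index()
        g["network"] = network
        g["weight"] = weight
        g = g.merge(rep, on="cell_id")
        return g[cols]

    out_aqs = _collapse(aqs, AQS, 1.0)
    aqs_keys = set(map(tuple, out_aqs[["cell_id", "hour"]].to_numpy())) if len(out_aqs) else set()
    if len(pa):
        keep = [
            (c, h) not in aqs_keys for c, h in zip(pa["cell_id"].to_numpy(), pa["hour"].to_numpy())
        ]
        pa = pa[np.asarray(keep, dtype=bool)]
    out_pa = _collapse(pa, PURPLEAIR, pa_weight)
    parts = [p for p in (out_aqs, out_pa) if len(p)]
    if not parts:
        return pd.DataFrame(columns=cols)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["cell_id", "hour"], kind="stable").reset_index(drop=True)


def fuse_grid(
    satellite: pd.DataFrame,
    met_points: pd.DataFrame,
    met_values: pd.DataFrame,
    static: pd.DataFrame,
    grid: pd.DataFrame,
) -> pd.DataFrame:
    """Full predictor table: one row per cell-hour with satellite,
    meteorology and static covariates (ground values are attached later)."""
    sat = aggregate_satellite_hourly(satellite)
    assignment = join_met_to_grid(met_points, grid)
    met = met_to_cell_hours(assignment, met_values)
    fused = met.merge(sat, on=["cell_id", "hour"], how="left").merge(static, on="cell_id", how="left")
    return fused.sort_values(["hour", "cell_id"], kind="stable").reset_index(drop=True)
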
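"""Model-ready feature table.

The predictor vector for each cell-hour combines the fused satellite,
meteorology and static covariates with a "convolutional layer": the
inverse-distance-weighted average of the nearest five ground measurements
from the same hour, which injects spatial autocorrelation into an otherwise
pointwise model. For a cell-hour that itself holds a measurement the
measurement is excluded from its own convolutional value (using it would
leak the target).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import BallTree

from .geo import EARTH_RADIUS_M

PREDICTORS = [
    "aod",
    "smoke_mask",
    "dust_mask",
    "aerosol_mask",
    "temperature_2m",
    "pressure",
    "u10",
    "v10",
    "pblh",
    "rh",
    "elevation",
    "road_dist_primary_km",
    "road_dist_secondary_km",
    "lu_developed",
    "lu_forest",
    "lu_shrub",
    "lu_cultivated",
    "conv_pm25",
]

BINARY_PREDICTORS = ["smoke_mask", "dust_mask", "aerosol_mask"]

DEFAULT_CONV_NEIGHBORS = 5


class FeatureError(RuntimeError):
    pass


def idw_neighbor_value(
    query_lon,
    query_lat,
    query_cell,
    obs_lon,
    obs_lat,
    obs_cell,
    obs_value,
    k: int = DEFAULT_CONV_NEIGHBORS,
    exclude_same_cell: bool = True,
) -> np.ndarray:
    """IDW average of the k nearest same-hour measurements for each query.

    Distances are great-circle between cell centers. A query's own cell is
    excluded when ``exclude_same_cell`` (training mode). Fewer than k
    neighbors ⇒ all available are used; zero neighbors ⇒ NaN; an exact
    zero distance returns that neighbor's value.
    """
    query_lon = np.atleast_1d(np.asarray(query_lon, dtype=float))
    query_lat = np.atleast_1d(np.asarray(query_lat, dtype=float))
    query_cell = np.atleast_1d(np.asarray(query_cell))
    obs_value = np.asarray(obs_value, dtype=float)
    obs_cell = np.asarray(obs_cell)
    n_obs = len(obs_value)
    out = np.full(len(query_lon), np.nan)
    if n_obs == 0:
        return out

    tree = BallTree(np.deg2rad(np.column_stack([obs_lat, obs_lon])), metric="haversine")
    kq = min(k + (1 if exclude_same_cell else 0), n_obs)
    dist, idx = tree.query(np.deg2rad(np.column_stack([query_lat, query_lon])), k=kq)
    dist = dist * EARTH_RADIUS_M

    for i in range(len(out)):
        di, ii = dist[i], idx[i]
        if exclude_same_cell:
            keep = obs_cell[ii] != query_cell[i]
            di, ii = di[keep], ii[keep]
            di, ii = di[:k], ii[:k]
        if len(ii) == 0:
            continue
        vals = obs_value[ii]
        zero = di <= 0.0
        if zero.any():
            out[i] = vals[zero][0]
            continue
        w = 1.0 / di
        out[i] = float(np.dot(w, vals) / w.sum())
    return out


def convolutional_layer(
    ground: pd.DataFrame,
    query: pd.DataFrame,
    grid: pd.DataFrame,
    k: int = DEFAULT_CONV_NEIGHBORS,
    exclude_same_cell: bool = True,
) -> np.ndarray:
    """Convolutional-layer values for ``query`` rows (cell_id, hour).

    ``ground`` is the deduplicated per-cell-hour measurement table; both
    frames are resolved to grid-cell centers before the distance search.
    Hours with no other measurement yield NaN (the row becomes incomplete).
    """
    centers = grid.set_index("cell_id")[["lon", "lat"]]
    out = np.full(len(query), np.nan)
    q_hours = query["hour"].to_numpy()
    g_by_hour = dict(tuple(ground.groupby("hour")))
    q_cell = query["cell_id"].to_numpy()
    q_lon = centers["lon"].reindex(q_cell).to_numpy()
    q_lat = centers["lat"].reindex(q_cell).to_numpy()
    for hour in np.unique(q_hours):
        g = g_by_hour.get(hour)
        if g is None or len(g) == 0:
            continue
        sel = q_hours == hour
        g_cell = g["cell_id"].to_numpy()
        out[sel] = idw_neighbor_value(
            q_lon[sel],
            q_lat[sel],
            q_cell[sel],
            centers["lon"].reindex(g_cell).to_numpy(),
            centers["lat"].reindex(g_cell).to_numpy(),
            g_cell,
            g["pm25"].to_numpy(),
            k=k,
            exclude_same_cell=exclude_same_cell,
        )
    return out


def build_training_table(
    fused: pd.DataFrame,
    ground: pd.DataFrame,
    grid: pd.DataFrame,
    k: int = DEFAULT_CONV_NEIGHBORS,
) -> pd.DataFrame:
    """One row per ground-observed cell-hour: target, weight, network,
    representative station, predictors and a ``complete`` flag.

    Training consumers use complete rows only; raises if none exists.
    """
    rows = ground.merge(fused, on=["cell_id", "hour"], how="left", suffixes=("", "_cell"))
    rows["conv_pm25"] = convolutional_layer(ground, rows, grid, k=k, exclude_same_cell=True)
    rows["complete"] = ~rows[PREDICTORS].isna().any(axis=1)
    rows["is_synthetic"] = False
    if not rows["complete"].any():
        raise FeatureError("zero complete training rows")
    return rows.reset_index(drop=True)


def build_prediction_rows(
    fused_hour: pd.DataFrame,
    ground: pd.DataFrame,
    grid: pd.DataFrame,
    k: int = DEFAULT_CONV_NEIGHBORS,
) -> pd.DataFrame:
    """One row per grid cell for a single hour of surface prediction.

    The convolutional layer uses all same-hour measurements (a cell being
    predicted holds no measurement of its own, so there is nothing to
    exclude); rows missing any predictor are flagged incomplete.
    """
    rows = fused_hour.copy()
    rows["conv_pm25"] = convolutional_layer(ground, rows, grid, k=k, exclude_same_cell=False)
    rows["complete"] = ~rows[PREDICTORS].isna().any(axis=1)
    return rows.reset_index(drop=True)
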
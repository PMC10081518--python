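"""Hourly PM2.5 prediction surfaces and their export.

A surface is the fitted model evaluated on every grid cell of one hour
whose predictor vector is complete (including the prediction-mode
convolutional layer built from all same-hour ground measurements);
incomplete cells are null and predictions are floored at 0 μg/m³. Surfaces
export as CSV or single-band GeoTIFF (WGS84 lon/lat geotransform, NaN
nodata).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .domain import DomainConfig
from .features import build_prediction_rows


@dataclass
class PredictionSurface:
    """Per-cell predictions for one hour on the (ny, nx) grid; NaN where any
    predictor is missing."""

    hour: int
    values: np.ndarray  # (ny, nx), NaN = no prediction
    provenance: dict = field(default_factory=dict)

    @property
    def n_predicted(self) -> int:
        return int(np.isfinite(self.values).sum())


def provenance_hash(config: DomainConfig) -> str:
    import dataclasses

    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def predict_hour(
    results,
    fused: pd.DataFrame,
    ground: pd.DataFrame,
    grid: pd.DataFrame,
    config: DomainConfig,
    hour: int,
) -> PredictionSurface:
    """Predict one hour's surface from a fitted `SmokePM25Results`."""
    fused_hour = fused[fused["hour"] == hour]
    rows = build_prediction_rows(fused_hour, ground[ground["hour"] == hour], grid)
    values = np.full(config.n_cells, np.nan)
    complete = rows["complete"].to_numpy()
    if not complete.any():
        warnings.warn(f"hour {hour}: no complete cells; empty surface")
    else:
        pred = results.predict(rows[complete])
        values[rows.loc[complete, "cell_id"].to_numpy()] = np.maximum(pred, 0.0)
    return PredictionSurface(
        hour=int(hour),
        values=values.reshape(config.ny, config.nx),
        provenance={
            "variant": results.model.variant,
            "seed": results.model.forest_config.seed,
            "config_hash": provenance_hash(config),
        },
    )


def export_surface(surface: PredictionSurface, grid: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a surface as ``csv`` (cell_id, lon, lat, hour, pm25) or
    ``gtiff`` (single-band float32, north-up, NaN nodata, WGS84)."""
    if format == "csv":
        ny, nx = surface.values.shape
        df = pd.DataFrame(
            {
                "cell_id": grid["cell_id"].to_numpy(),
                "lon": grid["lon"].to_numpy(),
                "lat": grid["lat"].to_numpy(),
                "hour": surface.hour,
                "pm25": surface.values.reshape(-1)[grid["cell_id"].to_numpy()],
            }
        )
        df.to_csv(path, index=False)
    elif format == "gtiff":
        ny, nx = surface.values.shape
        lon = grid["lon"].to_numpy().reshape(ny, nx)
        lat = grid["lat"].to_numpy().reshape(ny, nx)
        dlon = float(lon[0, 1] - lon[0, 0]) if nx > 1 else 1.0
        dlat = float(lat[1, 0] - lat[0, 0]) if ny > 1 else 1.0
        # north-up raster: row 0 = northernmost
        data = np.flipud(surface.values).astype(np.float32)
        lon_ul = float(lon[0, 0] - dlon / 2.0)
        lat_ul = float(lat[-1, 0] + abs(dlat) / 2.0)
        # minimal GeoTIFF tags: pixel scale, tiepoint, geographic WGS84 keys
        geokeys = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 2, 2048, 0, 1, 4326)
        extratags = [
            (33550, "d", 3, (abs(dlon), abs(dlat), 0.0)),
            (33922, "d", 6, (0.0, 0.0, 0.0, lon_ul, lat_ul, 0.0)),
            (34735, "H", len(geokeys), geokeys),
            (42113, "s", 0, "nan"),
        ]
        tifffile.imwrite(path, data, extratags=extratags)
    else:
        raise ValueError(f"unknown export format: {format!r}")


def read_surface_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_surface_gtiff(path) -> np.ndarray:
    return tifffile.imread(path)
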
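"""Low-cost sensor calibration by geographically weighted regression (GWR).

Low-cost optical PM sensors carry additive, humidity- and hardware-dependent
biases. Where a sensor sits within a small radius (default 500 m) of a
regulatory monitor, their same-hour measurements form collocated pairs; a
locally weighted regression of the regulatory value on the sensor value,
temperature, relative humidity, uptime and operating time, with Gaussian
spatial kernel weights around each collocation site, yields coefficient
surfaces that vary smoothly in space. Coefficients are transferred to
non-collocated sensors by kernel-weighted averaging of the anchor
coefficient vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_m, pairwise_haversine_m

logger = logging.getLogger(__name__)

GWR_FEATURES = ["pa_pm25", "temperature", "relative_humidity", "uptime", "operating_time"]

DEFAULT_COLLOCATION_RADIUS_M = 500.0


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationModel:
    """Local calibration coefficient surfaces.

    ``coefficients`` has one row per anchor (a unique sensor collocation
    site) ordered like ``anchors``; columns are (intercept, β_sensor,
    β_temp, β_rh, β_uptime, β_optime).
    """

    anchors: pd.DataFrame  # pa_station_id, lon, lat
    coefficients: np.ndarray  # (n_anchors, 6)
    kernel_bandwidth_km: float
    kernel_type: str = "gaussian"

    def __post_init__(self):
        if self.kernel_bandwidth_km <= 0:
            raise CalibrationError("kernel bandwidth must be > 0")
        if len(self.anchors) != len(self.coefficients):
            raise CalibrationError("one coefficient vector per anchor required")


def find_collocations(
    aqs_obs: pd.DataFrame, pa_obs: pd.DataFrame, radius_m: float = DEFAULT_COLLOCATION_RADIUS_M
) -> pd.DataFrame:
    """Pair each low-cost sensor with its nearest regulatory station within
    ``radius_m`` (great-circle), matched hour by hour.

    If several regulatory stations qualify, the nearest wins; distance ties
    break by station-id lexical order. Empty networks yield an empty frame.
    """
    cols = [
        "pa_station_id", "aqs_station_id", "distance_m", "hour",
        "pa_pm25", "aqs_pm25", "temperature", "relative_humidity",
        "uptime", "operating_time", "lon", "lat",
    ]
    if len(aqs_obs) == 0 or len(pa_obs) == 0:
        return pd.DataFrame(columns=cols)

    aqs_sites = (
        aqs_obs.groupby("station_id", as_index=False)[["lon", "lat"]].first().sort_values("station_id")
    )
    pa_sites = (
        pa_obs.groupby("station_id", as_index=False)[["lon", "lat"]].first().sort_values("station_id")
    )
    d = pairwise_haversine_m(pa_sites["lon"], pa_sites["lat"], aqs_sites["lon"], aqs_sites["lat"])
    # nearest qualifying AQS per sensor; lexical order (aqs_sites is sorted)
    # breaks exact distance ties because argmin returns the first minimum
    nearest = np.argmin(d, axis=1)
    dist = d[np.arange(len(pa_sites)), nearest]
    ok = dist <= radius_m
    if not ok.any():
        return pd.DataFrame(columns=cols)

    site_pairs = pd.DataFrame(
        {
            "pa_station_id": pa_sites["station_id"].to_numpy()[ok],
            "aqs_station_id": aqs_sites["station_id"].to_numpy()[nearest[ok]],
            "distance_m": dist[ok],
            "lon": pa_sites["lon"].to_numpy()[ok],
            "lat": pa_sites["lat"].to_numpy()[ok],
        }
    )
    pa_part = pa_obs[
        ["station_id", "hour", "pm25", "temperature", "relative_humidity", "uptime", "operating_time"]
    ].rename(columns={"station_id": "pa_station_id", "pm25": "pa_pm25"})
    aqs_part = aqs_obs[["station_id", "hour", "pm25"]].rename(
        columns={"station_id": "aqs_station_id", "pm25": "aqs_pm25"}
    )
    out = site_pairs.merge(pa_part, on="pa_station_id").merge(aqs_part, on=["aqs_station_id", "hour"])
    return out[cols].sort_values(["pa_station_id", "hour"]).reset_index(drop=True)


def _design(pairs: pd.DataFrame) -> np.ndarray:
    X = np.column_stack([np.ones(len(pairs))] + [pairs[c].to_numpy(float) for c in GWR_FEATURES])
    return X


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, int]:
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta, rank


def _gaussian_w(d_km: np.ndarray, bw_km: float) -> np.ndarray:
    if not np.isfinite(bw_km):
        return np.ones_like(d_km)
    return np.exp(-0.5 * (d_km / bw_km) ** 2)


def fit_gwr(pairs: pd.DataFrame, bandwidth_km: float | str = "auto") -> CalibrationModel:
    """Fit local calibration regressions at every collocation anchor.

    At each anchor, a weighted least squares of the regulatory measurement
    on (1, sensor, temperature, RH, uptime, operating time) uses Gaussian
    kernel weights over great-circle distance to every pair's sensor site.
    ``bandwidth_km='auto'`` selects the bandwidth minimizing
    leave-one-station-out CV RMSE over a logarithmic ladder. A locally
    rank-deficient design widens that anchor's kernel (doubling, up to 5
    times); if it stays singular an error names the anchor.
    """
    if len(pairs) == 0:
        raise CalibrationError("no collocated pairs to fit")
    pairs = pairs.dropna(subset=GWR_FEATURES + ["aqs_pm25"]).reset_index(drop=True)
    anchors = (
        pairs.groupby("pa_station_id", as_index=False)[["lon", "lat"]].first().sort_values("pa_station_id").reset_index(drop=True)
    )
    X = _design(pairs)
    y = pairs["aqs_pm25"].to_numpy(float)
    d_km = (
        pairwise_haversine_m(anchors["lon"], anchors["lat"], pairs["lon"], pairs["lat"]) / 1000.0
    )  # (n_anchors, n_pairs)

    if bandwidth_km == "auto":
        bandwidth_km = _select_bandwidth(pairs, anchors, X, y, d_km)
    bw = float(bandwidth_km)

    coefs = np.zeros((len(anchors), X.shape[1]))
    for i in range(len(anchors)):
        bw_i = bw
        for _ in range(6):
            w = _gaussian_w(d_km[i], bw_i)
            beta, rank = _wls(X, y, w)
            if rank == X.shape[1]:
                break
            bw_i *= 2.0
        else:
            raise CalibrationError(
                f"rank-deficient local design at anchor {anchors['pa_station_id'][i]}"
            )
        if bw_i != bw:
            logger.info("widened kernel at anchor %s to %.1f km", anchors["pa_station_id"][i], bw_i)
        coefs[i] = beta
    return CalibrationModel(anchors=anchors, coefficients=coefs, kernel_bandwidth_km=bw)


def _select_bandwidth(pairs, anchors, X, y, d_km) -> float:
    """Leave-one-station-out CV RMSE over a logarithmic bandwidth ladder."""
    ladder = np.logspace(np.log10(5.0), np.log10(500.0), 8)
    station = pairs["pa_station_id"].to_numpy()
    best_bw, best_rmse = ladder[-1], np.inf
    for bw in ladder:
        sq = 0.0
        n = 0
        ok = True
        for i, sid in enumerate(anchors["pa_station_id"]):
            hold = station == sid
            if hold.all() or not hold.any():
                continue
            w = _gaussian_w(d_km[i], bw)
            w_train = np.where(hold, 0.0, w)
            if np.count_nonzero(w_train > 1e-12) < X.shape[1]:
                ok = False
                break
            beta, rank = _wls(X, y, w_train)
            if rank < X.shape[1]:
                ok = False
                break
            resid = y[hold] - X[hold] @ beta
            sq += float(resid @ resid)
            n += int(hold.sum())
        if ok and n:
            rmse = np.sqrt(sq / n)
            if rmse < best_rmse:
                best_rmse, best_bw = rmse, bw
    return float(best_bw)


def coefficients_at(model: CalibrationModel, lon, lat) -> np.ndarray:
    """Coefficient surface evaluated at arbitrary points: kernel-weighted
    average of the anchor coefficient vectors (nearest anchor if all kernel
    weights underflow)."""
    d_km = pairwise_haversine_m(lon, lat, model.anchors["lon"], model.anchors["lat"]) / 1000.0
    w = _gaussian_w(d_km, model.kernel_bandwidth_km)
    wsum = w.sum(axis=1)
    out = np.empty((len(w), model.coefficients.shape[1]))
    good = wsum > 1e-300
    if good.any():
        out[good] = (w[good] / wsum[good, None]) @ model.coefficients
    if (~good).any():
        out[~good] = model.coefficients[np.argmin(d_km[~good], axis=1)]
    return out


def apply_calibration(model: CalibrationModel, pa_obs: pd.DataFrame) -> pd.DataFrame:
    """Calibrate raw sensor PM2.5 network-wide.

    Returns a copy with ``pm25_raw`` (the input value) and ``pm25`` replaced
    by the local linear prediction floored at 0 μg/m³. Rows missing any
    covariate are dropped (count logged).
    """
    out = pa_obs.copy()
    need = GWR_FEATURES[1:] + ["pm25"]
    missing = out[need].isna().any(axis=1)
    if missing.any():
        logger.warning("dropping %d sensor rows with missing covariates", int(missing.sum()))
        out = out[~missing].reset_index(drop=True)
    if len(out) == 0:
        out["pm25_raw"] = out.get("pm25", pd.Series(dtype=float))
        return out
    beta = coefficients_at(model, out["lon"].to_numpy(), out["lat"].to_numpy())
    X = np.column_stack(
        [
            np.ones(len(out)),
            out["pm25"].to_numpy(float),
            out["temperature"].to_numpy(float),
            out["relative_humidity"].to_numpy(float),
            out["uptime"].to_numpy(float),
            out["operating_time"].to_numpy(float),
        ]
    )
    pred = np.einsum("ij,ij->i", X, beta)
    out["pm25_raw"] = out["pm25"].to_numpy()
    out["pm25"] = np.maximum(pred, 0.0)
    return out
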
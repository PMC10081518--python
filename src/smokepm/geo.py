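"""Great-circle geometry and space-filling-curve helpers.

All station and grid-cell coordinates are handled as lon/lat degrees (WGS84);
distances between them are great-circle (haversine) distances in meters.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_008.8

KM_PER_DEG_LAT = 110.574


def km_per_deg_lon(lat: float) -> float:
    return 111.320 * np.cos(np.deg2rad(lat))


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in meters. Inputs broadcast; degrees."""
    lon1, lat1, lon2, lat2 = (np.deg2rad(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_m(lon_a, lat_a, lon_b, lat_b):
    """(len(a), len(b)) matrix of great-circle distances in meters."""
    lon_a = np.asarray(lon_a, dtype=float)[:, None]
    lat_a = np.asarray(lat_a, dtype=float)[:, None]
    lon_b = np.asarray(lon_b, dtype=float)[None, :]
    lat_b = np.asarray(lat_b, dtype=float)[None, :]
    return haversine_m(lon_a, lat_a, lon_b, lat_b)


def hilbert_index(x: np.ndarray, y: np.ndarray, order: int = 10) -> np.ndarray:
    """Distance along a Hilbert curve of the given order for integer coords.

    ``x``/``y`` must lie in [0, 2**order). Vectorized transcription of the
    classical xy -> d bit-twiddling loop.
    """
    x = np.asarray(x, dtype=np.int64).copy()
    y = np.asarray(y, dtype=np.int64).copy()
    d = np.zeros_like(x)
    s = np.int64(1) << (order - 1)
    while s > 0:
        rx = ((x & s) > 0).astype(np.int64)
        ry = ((y & s) > 0).astype(np.int64)
        d += s * s * ((3 * rx) ^ ry)
        # rotate quadrant
        swap = ry == 0
        flip = swap & (rx == 1)
        x_f, y_f = x.copy(), y.copy()
        x[flip] = s - 1 - x_f[flip]
        y[flip] = s - 1 - y_f[flip]
        x_s, y_s = x.copy(), y.copy()
        x[swap], y[swap] = y_s[swap], x_s[swap]
        s >>= 1
    return d


def hilbert_order_lonlat(lon, lat, order: int = 10) -> np.ndarray:
    """Hilbert-curve rank of points given in lon/lat degrees.

    Points are scaled into the curve's unit square using the bounding box of
    the inputs; degenerate (single-point or collinear) extents are handled by
    a unit span.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = (1 << order) - 1
    span_lon = max(lon.max() - lon.min(), 1e-9)
    span_lat = max(lat.max() - lat.min(), 1e-9)
    ix = np.clip(((lon - lon.min()) / span_lon * n).round().astype(np.int64), 0, n)
    iy = np.clip(((lat - lat.min()) / span_lat * n).round().astype(np.int64), 0, n)
    return hilbert_index(ix, iy, order=order)
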
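"""Synthetic wildfire-episode study domain.

Generates, from a single seed, everything the estimation pipeline consumes:
a modeling grid, an hourly "true" PM2.5 field (smooth regional background
plus a wind-advected Gaussian smoke plume), two ground networks (sparse
unbiased regulatory monitors and dense, clustered, biased low-cost sensors),
sub-hourly satellite products (AOD with retrieval failure in thick smoke,
smoke/dust/aerosol detection masks), hourly meteorology on an off-grid point
set, and static land-use/elevation/road covariates.

The generated data reproduce the statistical structure the estimation method
assumes: a right-skewed PM2.5 distribution with roughly 2% of ground
observations at or above 100 μg/m³, regulatory monitors reporting about six
hours per day, and low-cost sensors carrying an additive + humidity-dependent
bias of about +1.9 μg/m³ on average.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .geo import KM_PER_DEG_LAT, km_per_deg_lon

AQS = "AQS"
PURPLEAIR = "PURPLEAIR"


class ConfigError(ValueError):
    """Raised for invalid domain configurations."""


@dataclass(frozen=True)
class DomainConfig:
    """Parameters of the synthetic study domain.

    Distances are km, concentrations μg/m³, probabilities in [0, 1]. The
    default domain is 40×40 cells of 3×5 km over a 240-hour (~10 day)
    episode with 30 regulatory monitors and 240 low-cost sensors, preserving
    the ~1:8 regulatory:low-cost ratio of the California networks at desk
    scale.
    """

    nx: int = 40
    ny: int = 40
    cell_dx_km: float = 3.0
    cell_dy_km: float = 5.0
    n_hours: int = 240
    n_aqs: int = 30
    n_purpleair: int = 240
    plume_amplitude: float = 400.0
    plume_sigma_km: float = 11.0
    background_mean: float = 9.0
    background_sd: float = 6.0
    aqs_report_prob: float = 0.25
    pa_report_prob: float = 0.97
    pa_bias_add: float = 0.9
    pa_bias_rh_coef: float = 0.02
    pa_bias_mult: float = 0.0
    pa_noise_sd: float = 2.0
    aqs_noise_sd: float = 1.0
    aod_missing_frac_base: float = 0.15
    aod_scale: float = 0.01
    aod_noise_sd: float = 0.05
    smoke_threshold: float = 5.0
    sat_slots_per_hour: int = 3
    n_pa_clusters: int = 8
    pa_cluster_sigma_km: float = 4.0
    pa_collocated: int = 12
    origin_lon: float = -123.2
    origin_lat: float = 38.3
    seed: int = 0

    def __post_init__(self):
        for name in ("nx", "ny", "n_hours", "n_aqs", "n_purpleair"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("aqs_report_prob", "pa_report_prob", "aod_missing_frac_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.plume_sigma_km <= 0:
            raise ConfigError("plume_sigma_km must be > 0")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def extent_km(self) -> tuple[float, float]:
        return self.nx * self.cell_dx_km, self.ny * self.cell_dy_km

    def replace(self, **kw) -> "DomainConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "DomainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class TruthField:
    """True hourly PM2.5 on the grid, with the plume's kinematics.

    ``pm25`` and ``plume_component`` have shape (n_hours, ny, nx);
    ``pm25 = background + plume_component`` and is non-negative by
    construction. ``plume_center_track`` is the plume center in domain-km
    coordinates per hour; ``wind_uv`` the advecting wind (m/s).
    """

    pm25: np.ndarray
    plume_component: np.ndarray
    plume_center_track: np.ndarray
    wind_uv: np.ndarray

    @property
    def background(self) -> np.ndarray:
        return self.pm25 - self.plume_component


@dataclass
class Predictors:
    """Simulated predictor inputs prior to grid fusion."""

    satellite: pd.DataFrame   # sub-hourly records: cell_id, hour, slot, aod, aod_valid, smoke, dust, aerosol, mask_valid
    met_points: pd.DataFrame  # point_id, lon, lat (time-invariant point set)
    met_values: pd.DataFrame  # point_id, hour, temperature_2m, pressure, u10, v10, pblh, rh
    static: pd.DataFrame      # per-cell land-use fractions, elevation, road distances


def _rng(config: DomainConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def make_grid(config: DomainConfig) -> pd.DataFrame:
    """Cell table: cell_id, col, row, x_km, y_km (centers), lon, lat."""
    cols, rows = np.meshgrid(np.arange(config.nx), np.arange(config.ny))
    cols, rows = cols.ravel(), rows.ravel()
    x_km = (cols + 0.5) * config.cell_dx_km
    y_km = (rows + 0.5) * config.cell_dy_km
    lat_ref = config.origin_lat + config.extent_km[1] / 2.0 / KM_PER_DEG_LAT
    lon = config.origin_lon + x_km / km_per_deg_lon(lat_ref)
    lat = config.origin_lat + y_km / KM_PER_DEG_LAT
    return pd.DataFrame(
        {
            "cell_id": rows * config.nx + cols,
            "col": cols,
            "row": rows,
            "x_km": x_km,
            "y_km": y_km,
            "lon": lon,
            "lat": lat,
        }
    )


def _lonlat_from_km(config: DomainConfig, x_km, y_km):
    lat_ref = config.origin_lat + config.extent_km[1] / 2.0 / KM_PER_DEG_LAT
    return (
        config.origin_lon + np.asarray(x_km) / km_per_deg_lon(lat_ref),
        config.origin_lat + np.asarray(y_km) / KM_PER_DEG_LAT,
    )


def _cell_of_km(config: DomainConfig, x_km, y_km):
    col = np.clip((np.asarray(x_km) / config.cell_dx_km).astype(int), 0, config.nx - 1)
    row = np.clip((np.asarray(y_km) / config.cell_dy_km).astype(int), 0, config.ny - 1)
    return col, row


def _smooth_standard_field(rng, shape, sigma):
    """Zero-mean unit-sd Gaussian random field, smoothed over the given axes."""
    # periodic smoothing keeps the variance stationary (no inflated edges)
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def _fire_intensity(config: DomainConfig) -> np.ndarray:
    """Dimensionless episode intensity per hour: ignition ramp, diurnal
    flare-up peaking mid-afternoon, late-episode decay."""
    t = np.arange(config.n_hours, dtype=float)
    ramp = 1.0 - np.exp(-t / 18.0)
    decay_start = 0.8 * config.n_hours
    decay = np.exp(-np.maximum(0.0, t - decay_start) / (0.15 * config.n_hours + 1.0))
    diurnal = 0.75 + 0.25 * np.sin(2 * np.pi * (t % 24 - 8.0) / 24.0)
    return ramp * decay * diurnal


def generate_truth(config: DomainConfig) -> TruthField:
    """Simulate the true PM2.5 field.

    Background: exponentiated space-time-smoothed Gaussian noise with the
    configured lognormal mean/sd (guarantees positivity and right skew).
    Plume: a Gaussian blob of width ``plume_sigma_km`` whose amplitude
    follows the fire-intensity profile and whose center is advected each
    hour by an Ornstein-Uhlenbeck wind (x_{t+1} = x_t + u·Δt), reflected at
    the domain edges. Deterministic given (config, seed).
    """
    H, ny, nx = config.n_hours, config.ny, config.nx
    rng = _rng(config, 0)

    z = _smooth_standard_field(rng, (H, ny, nx), sigma=(6.0, 3.0, 3.0))
    mean, sd = config.background_mean, config.background_sd
    s2 = np.log1p((sd / mean) ** 2) if mean > 0 else 0.0
    mu = np.log(mean) - s2 / 2.0 if mean > 0 else -np.inf
    background = np.exp(mu + np.sqrt(s2) * z) if mean > 0 else np.zeros_like(z)

    # Plume center: prevailing-easterly sweep back and forth across the
    # domain with a slower north-south oscillation (random phases) plus an
    # OU meander; the advecting wind is derived from the track so that
    # x_{t+1} = x_t + u·Δt holds exactly.
    Lx, Ly = config.extent_km
    t = np.arange(H, dtype=float)
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, 2)
    x_path = Lx * (0.5 + 0.42 * np.cos(2 * np.pi * t / max(H, 1) * 2.0 + phase_x))
    y_path = Ly * (0.5 + 0.35 * np.sin(2 * np.pi * t / max(H, 1) * 1.3 + phase_y))
    meander = np.zeros((H, 2))
    state = np.zeros(2)
    for k in range(H):
        state = 0.9 * state + 1.2 * rng.standard_normal(2)
        meander[k] = state
    track = np.column_stack([x_path, y_path]) + meander
    track[:, 0] = np.clip(track[:, 0], 0.0, Lx)
    track[:, 1] = np.clip(track[:, 1], 0.0, Ly)
    uv = np.zeros((H, 2))
    if H > 1:
        uv[:-1] = (track[1:] - track[:-1]) / 3.6  # km/h → m/s
        uv[-1] = uv[-2]

    grid = make_grid(config)
    gx = grid["x_km"].to_numpy().reshape(ny, nx)
    gy = grid["y_km"].to_numpy().reshape(ny, nx)
    amp = config.plume_amplitude * _fire_intensity(config)
    d2 = (gx[None] - track[:, 0, None, None]) ** 2 + (gy[None] - track[:, 1, None, None]) ** 2
    plume = amp[:, None, None] * np.exp(-d2 / (2.0 * config.plume_sigma_km**2))
    if config.plume_amplitude == 0:
        plume = np.zeros_like(plume)

    return TruthField(
        pm25=background + plume,
        plume_component=plume,
        plume_center_track=track,
        wind_uv=uv,
    )


def _farthest_point_cells(rng, grid: pd.DataFrame, n: int) -> np.ndarray:
    """Quasi-uniform cell selection by greedy farthest-point sampling."""
    xy = grid[["x_km", "y_km"]].to_numpy()
    chosen = [int(rng.integers(len(grid)))]
    dmin = np.linalg.norm(xy - xy[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(dmin))
        chosen.append(nxt)
        dmin = np.minimum(dmin, np.linalg.norm(xy - xy[nxt], axis=1))
    return np.array(chosen)


def _uptime_series(rng, n_hours: int, mean_gap_h: float = 120.0) -> np.ndarray:
    """Hours since last boot, with reboot times from a Poisson process."""
    n_events = int(3 * n_hours / mean_gap_h) + 5
    reboots = -rng.uniform(0, mean_gap_h) + np.cumsum(rng.exponential(mean_gap_h, size=n_events))
    reboots = np.concatenate([[-rng.uniform(0, mean_gap_h)], reboots])
    hours = np.arange(n_hours, dtype=float)
    last = reboots[np.searchsorted(reboots, hours, side="right") - 1]
    return hours - last


def _diurnal_temp_c(hours: np.ndarray) -> np.ndarray:
    return 14.0 + 7.0 * np.sin(2 * np.pi * (hours % 24 - 9.0) / 24.0)


def sample_networks(config: DomainConfig, truth: TruthField) -> pd.DataFrame:
    """Draw hourly ground observations from both networks.

    Regulatory (AQS-like) monitors are placed quasi-uniformly, report each
    hour with ``aqs_report_prob`` and measure truth plus small zero-mean
    noise. Low-cost (PurpleAir-like) sensors sit in spatial clusters (a
    configurable handful within 500 m of a regulatory monitor, providing
    collocations for calibration), report nearly every hour, and measure

        truth·(1 + pa_bias_mult) + pa_bias_add + pa_bias_rh_coef·RH + noise,

    with per-sensor temperature/RH trajectories and uptime / operating-time
    hardware covariates attached. Every row carries the true PM2.5 at its
    cell-hour (``truth_pm25``) so recovery can be scored against the truth.
    """
    if max(config.n_aqs, config.n_purpleair) > config.n_cells:
        raise ConfigError("more stations than grid cells")
    rng = _rng(config, 1)
    grid = make_grid(config)
    H = config.n_hours
    hours = np.arange(H)
    Lx, Ly = config.extent_km

    # --- station placement -------------------------------------------------
    aqs_cells = _farthest_point_cells(rng, grid, config.n_aqs)
    aqs_x = grid["x_km"].to_numpy()[aqs_cells] + rng.uniform(-0.3, 0.3, config.n_aqs) * config.cell_dx_km
    aqs_y = grid["y_km"].to_numpy()[aqs_cells] + rng.uniform(-0.3, 0.3, config.n_aqs) * config.cell_dy_km

    n_pa = config.n_purpleair
    centers_idx = _farthest_point_cells(rng, grid, config.n_pa_clusters)
    cluster = np.arange(n_pa) % config.n_pa_clusters
    pa_x = grid["x_km"].to_numpy()[centers_idx][cluster] + rng.normal(0, config.pa_cluster_sigma_km, n_pa)
    pa_y = grid["y_km"].to_numpy()[centers_idx][cluster] + rng.normal(0, config.pa_cluster_sigma_km, n_pa)
    # collocate a handful of sensors with regulatory monitors (within 500 m)
    n_coll = min(config.pa_collocated, n_pa)
    host = rng.integers(0, config.n_aqs, size=n_coll) if n_coll else np.array([], dtype=int)
    r_m = rng.uniform(50.0, 400.0, size=n_coll)
    theta = rng.uniform(0, 2 * np.pi, size=n_coll)
    if n_coll:
        pa_x[:n_coll] = aqs_x[host] + (r_m / 1000.0) * np.cos(theta)
        pa_y[:n_coll] = aqs_y[host] + (r_m / 1000.0) * np.sin(theta)
    pa_x = np.clip(pa_x, 0.05, Lx - 0.05)
    pa_y = np.clip(pa_y, 0.05, Ly - 0.05)

    frames = []
    for network, sx, sy, report_p in (
        (AQS, aqs_x, aqs_y, config.aqs_report_prob),
        (PURPLEAIR, pa_x, pa_y, config.pa_report_prob),
    ):
        n_st = len(sx)
        col, row = _cell_of_km(config, sx, sy)
        lon, lat = _lonlat_from_km(config, sx, sy)
        truth_vals = truth.pm25[:, row, col]  # (H, n_st)
        report = rng.random((H, n_st)) < report_p
        t_idx, s_idx = np.nonzero(report)

        if network == AQS:
            pm = truth_vals + rng.normal(0, config.aqs_noise_sd, truth_vals.shape)
            temp = np.full(truth_vals.shape, np.nan)
            rh = np.full(truth_vals.shape, np.nan)
            uptime = np.full(truth_vals.shape, np.nan)
            optime = np.full(truth_vals.shape, np.nan)
        else:
            base_t = _diurnal_temp_c(hours)[:, None]
            temp = base_t + rng.normal(0, 1.5, n_st)[None, :] + rng.normal(0, 0.6, truth_vals.shape)
            rh = np.clip(
                50.0 - 1.8 * (temp - 14.0) + rng.normal(0, 4.0, n_st)[None, :] + rng.normal(0, 2.0, truth_vals.shape),
                10.0,
                100.0,
            )
            uptime = np.stack([_uptime_series(rng, H) for _ in range(n_st)], axis=1)
            install_age = rng.uniform(30.0, 600.0, n_st)
            optime = install_age[None, :] + hours[:, None] / 24.0
            pm = (
                truth_vals * (1.0 + config.pa_bias_mult)
                + config.pa_bias_add
                + config.pa_bias_rh_coef * rh
                + rng.normal(0, config.pa_noise_sd, truth_vals.shape)
            )
        pm = np.maximum(pm, 0.0)

        prefix = "aqs" if network == AQS else "pa"
        frames.append(
            pd.DataFrame(
                {
                    "station_id": np.array([f"{prefix}{i:04d}" for i in range(n_st)])[s_idx],
                    "network": network,
                    "lon": lon[s_idx],
                    "lat": lat[s_idx],
                    "col": col[s_idx],
                    "row": row[s_idx],
                    "cell_id": row[s_idx] * config.nx + col[s_idx],
                    "hour": t_idx,
                    "pm25": pm[t_idx, s_idx],
                    "truth_pm25": truth_vals[t_idx, s_idx],
                    "temperature": temp[t_idx, s_idx],
                    "relative_humidity": rh[t_idx, s_idx],
                    "uptime": uptime[t_idx, s_idx],
                    "operating_time": optime[t_idx, s_idx],
                }
            )
        )
    obs = pd.concat(frames, ignore_index=True)
    return obs.sort_values(["network", "station_id", "hour"], kind="stable").reset_index(drop=True)


def simulate_predictors(config: DomainConfig, truth: TruthField) -> Predictors:
    """Simulate satellite, meteorological and static predictor inputs.

    AOD is proportional to columnar (here: surface) PM2.5 plus noise, with
    retrieval failure probability increasing with aerosol loading so that
    missingness is informative inside the plume. Smoke masks fire where the
    plume component exceeds a detection threshold. Meteorology is produced
    on a jittered off-grid point set (one point per cell) so the injective
    nearest-neighbor join is genuinely exercised; winds are consistent with
    the plume-advecting wind.
    """
    rng = _rng(config, 2)
    grid = make_grid(config)
    H, ncell = config.n_hours, config.n_cells
    hours = np.arange(H)
    truth_flat = truth.pm25.reshape(H, ncell)
    plume_flat = truth.plume_component.reshape(H, ncell)

    # --- static covariates -------------------------------------------------
    ny, nx = config.ny, config.nx
    z_elev = _smooth_standard_field(rng, (ny, nx), sigma=4.0).ravel()
    elevation = np.clip(500.0 + 420.0 * z_elev, 0.0, None)
    road1 = 12.0 * np.exp(0.7 * _smooth_standard_field(rng, (ny, nx), sigma=3.0).ravel())
    road2 = 4.0 * np.exp(0.7 * _smooth_standard_field(rng, (ny, nx), sigma=2.0).ravel())
    lu_fields = np.stack(
        [_smooth_standard_field(rng, (ny, nx), sigma=3.0).ravel() for _ in range(4)]
    )
    lu = np.exp(1.2 * lu_fields)
    lu /= lu.sum(axis=0, keepdims=True)
    static = pd.DataFrame(
        {
            "cell_id": grid["cell_id"],
            "elevation": elevation,
            "road_dist_primary_km": road1,
            "road_dist_secondary_km": road2,
            "lu_developed": lu[0],
            "lu_forest": lu[1],
            "lu_shrub": lu[2],
            "lu_cultivated": lu[3],
        }
    )

    # --- sub-hourly satellite records -------------------------------------
    S = config.sat_slots_per_hour
    p_miss = np.clip(
        config.aod_missing_frac_base + 0.85 * (1.0 - np.exp(-truth_flat / 250.0)), 0.0, 0.98
    )
    recs = []
    for slot in range(S):
        aod = np.maximum(
            config.aod_scale * truth_flat + rng.normal(0, config.aod_noise_sd, truth_flat.shape), 0.0
        )
        aod_valid = rng.random(truth_flat.shape) >= p_miss
        smoke = (plume_flat > config.smoke_threshold) & (rng.random(truth_flat.shape) < 0.92)
        dust = rng.random(truth_flat.shape) < 0.01
        aerosol = (plume_flat > 2.0) | dust
        mask_valid = rng.random(truth_flat.shape) >= 0.10
        t_idx, c_idx = np.meshgrid(hours, np.arange(ncell), indexing="ij")
        recs.append(
            pd.DataFrame(
                {
                    "cell_id": c_idx.ravel().astype(np.int32),
                    "hour": t_idx.ravel().astype(np.int32),
                    "slot": np.int16(slot),
                    "aod": aod.ravel().astype(np.float32),
                    "aod_valid": aod_valid.ravel(),
                    "smoke": smoke.ravel().astype(np.int8),
                    "dust": dust.ravel().astype(np.int8),
                    "aerosol": aerosol.ravel().astype(np.int8),
                    "mask_valid": mask_valid.ravel(),
                }
            )
        )
    satellite = pd.concat(recs, ignore_index=True)

    # --- meteorology on an off-grid point set ------------------------------
    jit_x = rng.uniform(-1.0, 1.0, ncell)
    jit_y = rng.uniform(-1.0, 1.0, ncell)
    px = np.clip(grid["x_km"].to_numpy() + jit_x, 0.0, config.extent_km[0])
    py = np.clip(grid["y_km"].to_numpy() + jit_y, 0.0, config.extent_km[1])
    plon, plat = _lonlat_from_km(config, px, py)
    met_points = pd.DataFrame(
        {"point_id": [f"met{i:05d}" for i in range(ncell)], "lon": plon, "lat": plat}
    )

    z_sp = _smooth_standard_field(rng, (ny, nx), sigma=4.0).ravel()
    diurnal = _diurnal_temp_c(hours)[:, None]
    temp_k = (
        273.15
        + diurnal
        + 2.0 * z_sp[None, :]
        - 0.0065 * elevation[None, :]
        + rng.normal(0, 0.5, (H, ncell))
    )
    pressure = 101325.0 * np.exp(-elevation / 8434.0)[None, :] + rng.normal(0, 60.0, (H, ncell))
    u10 = truth.wind_uv[:, 0][:, None] + 0.8 * z_sp[None, :] + rng.normal(0, 0.3, (H, ncell))
    v10 = truth.wind_uv[:, 1][:, None] + 0.8 * z_sp[None, :] + rng.normal(0, 0.3, (H, ncell))
    pblh = np.clip(
        250.0
        + 900.0 * np.maximum(0.0, np.sin(np.pi * (hours % 24 - 6.0) / 12.0))[:, None]
        * (1.0 + 0.2 * z_sp[None, :])
        + rng.normal(0, 30.0, (H, ncell)),
        50.0,
        None,
    )
    rh = np.clip(
        90.0 - 2.2 * (temp_k - 273.15 - 5.0) + 5.0 * z_sp[None, :] + rng.normal(0, 2.0, (H, ncell)),
        5.0,
        100.0,
    )
    t_idx, p_idx = np.meshgrid(hours, np.arange(ncell), indexing="ij")
    met_values = pd.DataFrame(
        {
            "point_id": np.asarray(met_points["point_id"])[p_idx.ravel()],
            "hour": t_idx.ravel().astype(np.int32),
            "temperature_2m": temp_k.ravel().astype(np.float32),
            "pressure": pressure.ravel().astype(np.float32),
            "u10": u10.ravel().astype(np.float32),
            "v10": v10.ravel().astype(np.float32),
            "pblh": pblh.ravel().astype(np.float32),
            "rh": rh.ravel().astype(np.float32),
        }
    )

    return Predictors(satellite=satellite, met_points=met_points, met_values=met_values, static=static)


@dataclass
class SyntheticDomain:
    """Bundle of everything the generator produces for one (config, seed)."""

    config: DomainConfig
    grid: pd.DataFrame
    truth: TruthField
    observations: pd.DataFrame
    predictors: Predictors


def simulate_domain(config: DomainConfig) -> SyntheticDomain:
    truth = generate_truth(config)
    obs = sample_networks(config, truth)
    preds = simulate_predictors(config, truth)
    return SyntheticDomain(config=config, grid=make_grid(config), truth=truth, observations=obs, predictors=preds)


def write_domain(domain: SyntheticDomain, out_dir) -> None:
    """Write the domain as plain CSV files with a stable column schema."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    domain.config.to_yaml(out / "config.yaml")
    domain.grid.to_csv(out / "grid.csv", index=False)
    domain.observations.to_csv(out / "observations.csv", index=False)
    domain.predictors.satellite.to_csv(out / "satellite.csv", index=False)
    domain.predictors.met_points.to_csv(out / "met_points.csv", index=False)
    domain.predictors.met_values.to_csv(out / "met_values.csv", index=False)
    domain.predictors.static.to_csv(out / "static.csv", index=False)
    H, ny, nx = domain.truth.pm25.shape
    truth_df = pd.DataFrame(
        {
            "hour": np.repeat(np.arange(H), ny * nx),
            "cell_id": np.tile(np.arange(ny * nx), H),
            "pm25": domain.truth.pm25.reshape(-1),
        }
    )
    truth_df.to_csv(out / "truth.csv", index=False)
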
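"""Collocation pairing and GWR calibration: pairing rules, limiting cases,
parameter recovery against known sensor bias, and bias removal."""

import numpy as np
import pandas as pd
import pytest

from smokepm import apply_calibration, find_collocations, fit_gwr
from smokepm.calibration import CalibrationModel, GWR_FEATURES, coefficients_at
from smokepm.geo import pairwise_haversine_m

from conftest import make_obs_frame

# ~0.000905° of latitude ≈ 100 m
DEG_100M = 100.0 / 110_574.0


def _obs(station, network, dlat_m, hour, pm25, lon0=-122.0, lat0=39.0):
    return (station, network, lon0, lat0 + dlat_m * DEG_100M / 100.0, hour, pm25)


class TestFindCollocations:
    def test_pair_within_radius_included(self):
        aqs = make_obs_frame([_obs("a1", "AQS", 0, 5, 12.0)])
        pa = make_obs_frame([_obs("p1", "PURPLEAIR", 400, 5, 14.0)])
        pairs = find_collocations(aqs, pa, radius_m=500)
        assert len(pairs) == 1
        assert pairs.loc[0, "aqs_station_id"] == "a1"
        assert 390 < pairs.loc[0, "distance_m"] < 410

    def test_pair_beyond_radius_excluded(self):
        aqs = make_obs_frame([_obs("a1", "AQS", 0, 5, 12.0)])
        pa = make_obs_frame([_obs("p1", "PURPLEAIR", 600, 5, 14.0)])
        assert len(find_collocations(aqs, pa, radius_m=500)) == 0

    def test_hour_mismatch_excluded(self):
        aqs = make_obs_frame([_obs("a1", "AQS", 0, 5, 12.0)])
        pa = make_obs_frame([_obs("p1", "PURPLEAIR", 100, 6, 14.0)])
        assert len(find_collocations(aqs, pa)) == 0

    def test_nearest_aqs_wins(self):
        # brute-force oracle: enumerate all qualifying pairs, keep min distance
        aqs = make_obs_frame(
            [_obs("a_far", "AQS", 300, 5, 12.0), _obs("a_near", "AQS", 100, 5, 11.0)]
        )
        pa = make_obs_frame([_obs("p1", "PURPLEAIR", 0, 5, 14.0)])
        pairs = find_collocations(aqs, pa, radius_m=500)
        d = pairwise_haversine_m(pa["lon"][:1], pa["lat"][:1], aqs["lon"], aqs["lat"])[0]
        expected = aqs["station_id"].iloc[int(np.argmin(d))]
        assert pairs["aqs_station_id"].unique().tolist() == [expected] == ["a_near"]

    def test_empty_networks_yield_empty(self):
        aqs = make_obs_frame([_obs("a1", "AQS", 0, 5, 12.0)])
        empty = aqs.iloc[:0]
        assert len(find_collocations(aqs, empty)) == 0
        assert len(find_collocations(empty, aqs)) == 0


def _paired_frame(rng, n=400, n_stations=4, spread_deg=0.3):
    """Collocated pairs with configurable sensor response pa = a + b·truth."""
    lons = -122.0 + spread_deg * rng.random(n_stations)
    lats = 39.0 + spread_deg * rng.random(n_stations)
    sid = rng.integers(0, n_stations, n)
    truth = rng.gamma(3.0, 8.0, n)
    return lons, lats, sid, truth


def _pairs_df(lons, lats, sid, truth, pa_vals, aqs_vals, rng):
    n = len(sid)
    return pd.DataFrame(
        {
            "pa_station_id": [f"p{s}" for s in sid],
            "aqs_station_id": [f"a{s}" for s in sid],
            "distance_m": 100.0,
            "hour": np.arange(n) % 24,
            "pa_pm25": pa_vals,
            "aqs_pm25": aqs_vals,
            "temperature": 15 + rng.normal(0, 3, n),
            "relative_humidity": 50 + rng.normal(0, 8, n),
            "uptime": rng.uniform(0, 200, n),
            "operating_time": rng.uniform(30, 600, n),
            "lon": lons[sid],
            "lat": lats[sid],
        }
    )


class TestFitGWR:
    def test_infinite_bandwidth_equals_global_ols(self):
        rng = np.random.default_rng(0)
        lons, lats, sid, truth = _paired_frame(rng)
        pa = 2.0 + 1.1 * truth + rng.normal(0, 0.5, len(sid))
        aqs = truth + rng.normal(0, 0.3, len(sid))
        pairs = _pairs_df(lons, lats, sid, truth, pa, aqs, rng)
        model = fit_gwr(pairs, bandwidth_km=np.inf)
        X = np.column_stack([np.ones(len(pairs))] + [pairs[c] for c in GWR_FEATURES])
        beta_ols, *_ = np.linalg.lstsq(X, pairs["aqs_pm25"], rcond=None)
        for row in model.coefficients:
            np.testing.assert_allclose(row, beta_ols, atol=1e-8)

    def test_global_linear_bias_recovered(self):
        # pa = a + b·truth exactly; aqs = truth ⇒ β_pa = 1/b, intercept = −a/b
        rng = np.random.default_rng(1)
        a, b = 3.0, 1.25
        lons, lats, sid, truth = _paired_frame(rng, n=600)
        pairs = _pairs_df(lons, lats, sid, truth, a + b * truth, truth, rng)
        model = fit_gwr(pairs, bandwidth_km=30.0)
        beta_pa = model.coefficients[:, 1]
        intercept = model.coefficients[:, 0]
        np.testing.assert_allclose(beta_pa, 1.0 / b, rtol=0.05)
        np.testing.assert_allclose(intercept, -a / b, rtol=0.05)

    def test_identity_sensor_gives_identity_coefficients(self):
        rng = np.random.default_rng(2)
        lons, lats, sid, truth = _paired_frame(rng, n=500)
        pairs = _pairs_df(lons, lats, sid, truth, truth, truth, rng)
        model = fit_gwr(pairs, bandwidth_km=50.0)
        np.testing.assert_allclose(model.coefficients[:, 1], 1.0, atol=1e-6)
        np.testing.assert_allclose(model.coefficients[:, 0], 0.0, atol=1e-5)
        np.testing.assert_allclose(model.coefficients[:, 2:], 0.0, atol=1e-6)

    def test_auto_bandwidth_selects_from_ladder(self):
        rng = np.random.default_rng(3)
        lons, lats, sid, truth = _paired_frame(rng, n=500)
        pa = 2.0 + 1.1 * truth + rng.normal(0, 0.5, len(sid))
        pairs = _pairs_df(lons, lats, sid, truth, pa, truth, rng)
        model = fit_gwr(pairs, bandwidth_km="auto")
        assert 5.0 <= model.kernel_bandwidth_km <= 500.0


class TestApplyCalibration:
    def _model_with(self, coefs):
        anchors = pd.DataFrame({"pa_station_id": ["p0"], "lon": [-122.0], "lat": [39.0]})
        return CalibrationModel(
            anchors=anchors, coefficients=np.array([coefs]), kernel_bandwidth_km=50.0
        )

    def test_identity_coefficients_return_raw(self):
        model = self._model_with([0, 1, 0, 0, 0, 0])
        pa = make_obs_frame([_obs("p1", "PURPLEAIR", 0, 5, 23.4)])
        out = apply_calibration(model, pa)
        np.testing.assert_allclose(out["pm25"], out["pm25_raw"])
        np.testing.assert_allclose(out["pm25"], 23.4)

    def test_negative_prediction_floored(self):
        model = self._model_with([-100.0, 1, 0, 0, 0, 0])
        pa = make_obs_frame([_obs("p1", "PURPLEAIR", 0, 5, 23.4)])
        assert apply_calibration(model, pa)["pm25"].iloc[0] == 0.0

    def test_missing_covariate_row_dropped(self):
        model = self._model_with([0, 1, 0, 0, 0, 0])
        pa = make_obs_frame(
            [_obs("p1", "PURPLEAIR", 0, 5, 23.4), _obs("p2", "PURPLEAIR", 0, 6, 9.9)]
        )
        pa.loc[1, "relative_humidity"] = np.nan
        out = apply_calibration(model, pa)
        assert len(out) == 1 and out["station_id"].iloc[0] == "p1"

    def test_coefficient_transfer_smooth(self):
        anchors = pd.DataFrame(
            {"pa_station_id": ["p0", "p1"], "lon": [-122.0, -121.0], "lat": [39.0, 39.0]}
        )
        model = CalibrationModel(
            anchors=anchors,
            coefficients=np.array([[0, 1.0, 0, 0, 0, 0], [0, 2.0, 0, 0, 0, 0]]),
            kernel_bandwidth_km=50.0,
        )
        beta = coefficients_at(model, np.array([-121.5]), np.array([39.0]))
        assert 1.0 < beta[0, 1] < 2.0


class TestBiasRemoval:
    def test_calibration_reduces_bias_and_rmse(self, pipeline):
        cal = pipeline.calibrated_obs
        pa = cal[cal["network"] == "PURPLEAIR"]
        raw_err = pa["pm25_raw"] - pa["truth_pm25"]
        cal_err = pa["pm25"] - pa["truth_pm25"]
        assert abs(cal_err.mean()) < abs(raw_err.mean())
        assert np.sqrt((cal_err**2).mean()) < np.sqrt((raw_err**2).mean())
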
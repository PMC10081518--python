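"""Grid fusion: hourly satellite aggregation, injective meteorology join,
and ground deduplication with network precedence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from smokepm import aggregate_satellite_hourly, dedup_ground, join_met_to_grid
from smokepm.fusion import FusionError, MET_FIELDS, met_to_cell_hours
from smokepm.geo import pairwise_haversine_m


def sat_records(rows):
    return pd.DataFrame(
        rows,
        columns=["cell_id", "hour", "slot", "aod", "aod_valid", "smoke", "dust", "aerosol", "mask_valid"],
    )


class TestAggregateSatellite:
    def test_aod_mean_of_valid(self):
        rec = sat_records(
            [(0, 3, 0, 0.2, True, 0, 0, 0, True), (0, 3, 1, 0.4, True, 0, 0, 0, True)]
        )
        out = aggregate_satellite_hourly(rec)
        assert out.loc[0, "aod"] == pytest.approx(0.3)

    def test_mask_any_rule(self):
        rec = sat_records(
            [
                (0, 3, 0, 0.1, True, 0, 0, 0, True),
                (0, 3, 1, 0.1, True, 1, 0, 0, True),
                (0, 3, 2, 0.1, True, 0, 0, 0, True),
            ]
        )
        out = aggregate_satellite_hourly(rec)
        assert out.loc[0, "smoke_mask"] == 1.0
        assert out.loc[0, "dust_mask"] == 0.0

    def test_partial_validity_uses_only_valid(self):
        # 12 five-minute slots, 7 valid: mean over the 7 (direct oracle)
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 12)
        valid = np.zeros(12, dtype=bool)
        valid[rng.choice(12, 7, replace=False)] = True
        rec = sat_records(
            [(5, 1, s, vals[s], valid[s], 0, 0, 0, True) for s in range(12)]
        )
        out = aggregate_satellite_hourly(rec)
        assert out.loc[0, "aod"] == pytest.approx(vals[valid].mean())

    def test_no_valid_records_null(self):
        rec = sat_records([(0, 3, 0, 0.2, False, 1, 0, 1, False)])
        out = aggregate_satellite_hourly(rec)
        assert np.isnan(out.loc[0, "aod"]) and np.isnan(out.loc[0, "smoke_mask"])

    def test_empty_input(self):
        out = aggregate_satellite_hourly(sat_records([]))
        assert len(out) == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        rec = sat_records(
            [
                (int(rng.integers(3)), int(rng.integers(2)), s, rng.uniform(), bool(rng.integers(2)),
                 int(rng.integers(2)), 0, int(rng.integers(2)), bool(rng.integers(2)))
                for s in range(40)
            ]
        )
        a = aggregate_satellite_hourly(rec)
        b = aggregate_satellite_hourly(rec.sample(frac=1, random_state=5))
        pd.testing.assert_frame_equal(a, b)


def _points(coords, prefix="m"):
    return pd.DataFrame(
        {
            "point_id": [f"{prefix}{i}" for i in range(len(coords))],
            "lon": [c[0] for c in coords],
            "lat": [c[1] for c in coords],
        }
    )


def _cells(coords):
    return pd.DataFrame(
        {"cell_id": np.arange(len(coords)), "lon": [c[0] for c in coords], "lat": [c[1] for c in coords]}
    )


def brute_force_min_assignment(points, cells):
    """Exhaustive minimum-total-distance injective assignment (small only)."""
    d = pairwise_haversine_m(points["lon"], points["lat"], cells["lon"], cells["lat"])
    P, C = d.shape
    best, best_cost = None, np.inf
    if P <= C:
        for combo in itertools.permutations(range(C), P):
            cost = d[np.arange(P), list(combo)].sum()
            if cost < best_cost:
                best_cost, best = cost, combo
    return best, best_cost, d


class TestJoinMet:
    def test_points_at_centers_identity(self):
        coords = [(-122 + 0.1 * i, 39 + 0.05 * j) for j in range(3) for i in range(3)]
        out = join_met_to_grid(_points(coords), _cells(coords)).table
        assert (out["point_id"] == [f"m{i}" for i in range(9)]).all()
        assert not out["inherited"].any()

    def test_contested_cell_resolved(self):
        # both points nearest cell A; greedy gives A to the closer point,
        # B to the other — matching the exhaustive optimum here
        cells = _cells([(-122.0, 39.0), (-122.0, 39.5)])  # A, B
        points = _points([(-122.0, 39.01), (-122.0, 39.05)])
        out = join_met_to_grid(points, cells).table
        assert out.loc[0, "point_id"] == "m0"
        assert out.loc[1, "point_id"] == "m1"
        best, *_ = brute_force_min_assignment(points, cells)
        assert tuple(out.sort_values("cell_id")["point_id"]) == tuple(f"m{p}" for p in np.argsort(best))

    def test_injectivity_and_cardinality_random(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            P, C = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            points = _points(list(zip(-122 + rng.random(P), 39 + rng.random(P))))
            cells = _cells(list(zip(-122 + rng.random(C), 39 + rng.random(C))))
            res = join_met_to_grid(points, cells)
            direct = res.table[~res.table["inherited"]]
            assert res.n_direct == min(P, C)
            assert direct["point_id"].nunique() == len(direct) == min(P, C)
            if P <= C:
                _, best_cost, d = brute_force_min_assignment(points, cells)
                # greedy is near the exhaustive minimum-distance assignment
                greedy_cost = direct["distance_m"].sum()
                assert greedy_cost <= 2.0 * best_cost + 1e-9

    def test_more_cells_than_points_inherits(self):
        cells = _cells([(-122.0, 39.0), (-122.0, 39.3), (-122.0, 39.6)])
        points = _points([(-122.0, 39.0)])
        res = join_met_to_grid(points, cells)
        assert res.n_direct == 1
        assert res.table["inherited"].sum() == 2
        assert (res.table["point_id"] == "m0").all()

    def test_zero_points_error(self):
        with pytest.raises(FusionError):
            join_met_to_grid(_points([]), _cells([(-122.0, 39.0)]))

    def test_met_values_expand(self):
        cells = _cells([(-122.0, 39.0), (-122.0, 39.3)])
        points = _points([(-122.0, 39.0), (-122.0, 39.3)])
        assignment = join_met_to_grid(points, cells)
        vals = pd.DataFrame(
            {
                "point_id": ["m0", "m1"],
                "hour": [0, 0],
                **{f: [1.0, 2.0] for f in MET_FIELDS},
            }
        )
        out = met_to_cell_hours(assignment, vals)
        assert len(out) == 2 and set(out.columns) == {"cell_id", "hour", *MET_FIELDS}


def ground(rows):
    df = pd.DataFrame(rows, columns=["station_id", "network", "cell_id", "hour", "pm25"])
    df["lon"] = -122.0
    df["lat"] = 39.0
    return df


class TestDedupGround:
    def test_aqs_supersedes_purpleair(self):
        out = dedup_ground(ground([("a1", "AQS", 0, 0, 10.0), ("p1", "PURPLEAIR", 0, 0, 20.0)]))
        assert len(out) == 1
        row = out.iloc[0]
        assert row["pm25"] == 10.0 and row["network"] == "AQS" and row["weight"] == 1.0

    def test_purpleair_mean_and_weight(self):
        out = dedup_ground(
            ground([("p1", "PURPLEAIR", 0, 0, 20.0), ("p2", "PURPLEAIR", 0, 0, 30.0)])
        )
        row = out.iloc[0]
        assert row["pm25"] == 25.0 and row["network"] == "PURPLEAIR" and row["weight"] == 0.15

    def test_same_network_mean(self):
        out = dedup_ground(ground([("a1", "AQS", 0, 0, 8.0), ("a2", "AQS", 0, 0, 12.0)]))
        assert out.iloc[0]["pm25"] == 10.0 and out.iloc[0]["weight"] == 1.0

    def test_output_count_equals_distinct_cell_hours(self, pipeline):
        obs = pipeline.calibrated_obs
        out = pipeline.ground
        assert len(out) == obs.groupby(["cell_id", "hour"]).ngroups
        assert not out.duplicated(["cell_id", "hour"]).any()

    def test_aqs_supersession_only_within_same_hour(self):
        out = dedup_ground(
            ground([("a1", "AQS", 0, 0, 10.0), ("p1", "PURPLEAIR", 0, 1, 20.0)])
        )
        assert len(out) == 2
        assert set(out["network"]) == {"AQS", "PURPLEAIR"}
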
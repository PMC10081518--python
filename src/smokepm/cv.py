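"""Temporal blocked and spatial leave-group-out cross-validation.

Temporal: rows sorted by time are cut into k contiguous blocks, so training
and validation never share a time window. Spatial: monitors are ordered
along a Hilbert curve over lon/lat and dealt round-robin into groups of
ten, making every group span the domain; all of a monitor's rows travel
with its group, so no station appears on both sides of a split. With the
SMOTE variant, augmentation happens inside each fold's training part only —
synthetic rows are never scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import WeightedRandomForest
from .geo import hilbert_order_lonlat
from .model import EvalMetrics, SmokePM25Model, evaluate
from .resampling import label_minority, smote_augment

logger = logging.getLogger(__name__)

TEMPORAL_10FOLD = "temporal_10fold"
SPATIAL_LEAVE_TEN_OUT = "spatial_leave_ten_out"


@dataclass
class FoldPlan:
    """Partition of observations for cross-validation.

    ``row_folds`` maps each row of the planned table (by position) to a fold
    id; for spatial plans ``station_groups`` additionally maps station id →
    group id.
    """

    kind: str
    row_folds: np.ndarray
    station_groups: dict[str, int] | None = None

    @property
    def n_folds(self) -> int:
        return int(self.row_folds.max()) + 1 if len(self.row_folds) else 0


def make_temporal_folds(table: pd.DataFrame, k: int = 10) -> FoldPlan:
    """k contiguous near-equal blocks after a stable sort by (hour,
    station id); block sizes differ by at most one, larger blocks first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.lexsort(
        (table["station_id"].astype(str).to_numpy(), table["hour"].to_numpy())
    )
    n = len(table)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    fold_of_sorted = np.repeat(np.arange(k), sizes)
    row_folds = np.empty(n, dtype=int)
    row_folds[order] = fold_of_sorted
    return FoldPlan(kind=TEMPORAL_10FOLD, row_folds=row_folds)


def make_spatial_folds(
    table: pd.DataFrame, monitors: pd.DataFrame | None = None, group_size: int = 10
) -> FoldPlan:
    """Leave-``group_size``-monitors-out groups, spatially heterogeneous.

    Monitors (station_id, lon, lat; derived from the table if not given)
    are ranked along a Hilbert curve and dealt round-robin into
    ceil(M / group_size) groups, so consecutive (nearby) monitors land in
    different groups and each group spreads across the domain.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if monitors is None:
        monitors = table.groupby("station_id", as_index=False)[["lon", "lat"]].first()
    monitors = monitors.sort_values("station_id").reset_index(drop=True)
    M = len(monitors)
    n_groups = max(1, -(-M // group_size))
    rank = np.lexsort(
        (
            monitors["station_id"].astype(str).to_numpy(),
            hilbert_order_lonlat(monitors["lon"], monitors["lat"]),
        )
    )
    groups = np.empty(M, dtype=int)
    groups[rank] = np.arange(M) % n_groups
    station_groups = dict(zip(monitors["station_id"], groups))
    row_folds = table["station_id"].map(station_groups).to_numpy(int)
    return FoldPlan(
        kind=SPATIAL_LEAVE_TEN_OUT, row_folds=row_folds, station_groups=station_groups
    )


@dataclass
class CVResults:
    """Pooled held-out predictions and their agreement metrics."""

    plan_kind: str
    variant: str
    predictions: pd.DataFrame  # cell_id, hour, station_id, fold, measured, predicted
    report: EvalMetrics

    def summary(self) -> str:
        m = self.report
        return (
            f"{self.plan_kind} CV, variant={self.variant}: "
            f"R2={m.r2:.3f} RMSE={m.rmse:.2f} ug/m3 "
            f"slope={m.slope:.3f} intercept={m.intercept:.2f} "
            f"high-range slope={m.high_range_slope:.3f} (n={m.high_range_n})"
        )


def cross_validate(model: SmokePM25Model, plan: FoldPlan) -> CVResults:
    """Fold-wise refit and held-out prediction.

    Each fold's model trains on all other folds (with SMOTE, if configured,
    applied to that training part only) and predicts the held-out rows;
    predictions are pooled and scored on original rows exclusively. A fold
    whose training part has no minority rows skips SMOTE with a warning.
    """
    rows = model.table
    folds = np.asarray(plan.row_folds)
    if len(folds) != len(rows):
        raise ValueError("fold plan does not cover the model table")
    uniq = np.unique(folds)
    if len(uniq) < 2:
        raise ValueError("cross-validation needs at least 2 folds")

    fc = model.forest_config
    p = len(model.predictors)
    preds = np.full(len(rows), np.nan)
    for f in uniq:
        hold = folds == f
        train = rows[~hold]
        if len(train) == 0:
            raise ValueError(f"fold {f} leaves no training rows")
        if model.variant == "aqs_pa_smote" and model.smote is not None:
            if label_minority(train[model.target], model.smote.minority_cutoff).sum() == 0:
                warnings.warn(f"fold {f}: no minority rows in training part; SMOTE skipped")
            else:
                train = smote_augment(
                    train, model.smote, predictors=model.predictors, target=model.target
                )
        forest = WeightedRandomForest(
            n_trees=fc.n_trees,
            m_try=fc.resolve_m_try(p),
            min_node_size=fc.min_node_size,
            max_depth=fc.max_depth,
            seed=_fold_seed(fc.seed, int(f)),
        ).fit(
            train[model.predictors].to_numpy(float),
            train[model.target].to_numpy(float),
            sample_weight=train["weight"].to_numpy(float) if "weight" in train.columns else None,
        )
        preds[hold] = forest.predict(rows.loc[hold, model.predictors].to_numpy(float))

    out = pd.DataFrame(
        {
            "cell_id": rows.get("cell_id"),
            "hour": rows.get("hour"),
            "station_id": rows.get("station_id"),
            "fold": folds,
            "measured": rows[model.target].to_numpy(float),
            "predicted": preds,
        }
    )
    return CVResults(
        plan_kind=plan.kind,
        variant=model.variant,
        predictions=out,
        report=evaluate(out["measured"], out["predicted"]),
    )


def _fold_seed(base_seed: int, fold: int) -> int:
    """Deterministic per-fold forest seed derived from the base seed."""
    return int(np.random.SeedSequence([int(base_seed), fold]).generate_state(1)[0] % (2**31))
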
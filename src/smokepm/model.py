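"""Statistical modeling surface: model + results objects.

`SmokePM25Model` wraps a model-ready feature table and one of the three
estimation variants:

  ``aqs``            regulatory measurements only (all weights 1);
  ``aqs_pa``         regulatory + calibrated low-cost measurements, the
                     latter down-weighted (default 0.15) via the forest's
                     weight-proportional bootstrap;
  ``aqs_pa_smote``   as above, with SMOTE augmentation of the rare
                     high-concentration rows applied to the training data.

`fit()` returns a `SmokePM25Results` carrying the fitted ensemble, out-of-bag
predictions and goodness-of-fit metrics (R² as the squared Pearson
correlation of measured vs predicted, RMSE, and the slope/intercept of the
measured-vs-predicted regression, including the slope restricted to the
high range at/above the minority cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import PREDICTORS
from .forest import WeightedRandomForest
from .resampling import MINORITY_CUTOFF, SmoteConfig, smote_augment

VARIANTS = ("aqs", "aqs_pa", "aqs_pa_smote")


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters: 500 trees, m_try = ceil(sqrt(p)), minimum
    node size 5 and maximum depth 20 unless overridden."""

    n_trees: int = 500
    m_try: int | None = None
    min_node_size: int = 5
    max_depth: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_m_try(self, p: int) -> int:
        return self.m_try if self.m_try is not None else math.ceil(math.sqrt(p))


@dataclass
class EvalMetrics:
    """Measured-vs-predicted agreement metrics for one evaluation scheme."""

    r2: float
    rmse: float
    slope: float
    intercept: float
    n: int
    high_range_slope: float = float("nan")
    high_range_n: int = 0
    cutoff: float = MINORITY_CUTOFF

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "high_range_slope": self.high_range_slope,
            "high_range_n": self.high_range_n,
        }


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 2 or np.std(x) == 0:
        return float("nan"), float("nan")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def evaluate(measured, predicted, cutoff: float = MINORITY_CUTOFF) -> EvalMetrics:
    """Agreement metrics between measured and predicted concentrations.

    R² is the squared Pearson correlation; the slope/intercept come from an
    OLS fit of predicted on measured (the dotted line of a
    measured-vs-predicted scatter); the high-range slope repeats that fit on
    the subset with measured >= cutoff.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ok = ~(np.isnan(measured) | np.isnan(predicted))
    measured, predicted = measured[ok], predicted[ok]
    n = len(measured)
    if n < 2 or np.std(measured) == 0 or np.std(predicted) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(measured, predicted)[0, 1] ** 2)
    rmse = float(np.sqrt(np.mean((measured - predicted) ** 2))) if n else float("nan")
    slope, intercept = _ols_line(measured, predicted)
    hi = measured >= cutoff
    hi_slope, _ = _ols_line(measured[hi], predicted[hi])
    return EvalMetrics(
        r2=r2,
        rmse=rmse,
        slope=slope,
        intercept=intercept,
        n=n,
        high_range_slope=hi_slope,
        high_range_n=int(hi.sum()),
        cutoff=cutoff,
    )


class SmokePM25Model:
    """Weighted-random-forest PM2.5 model over a feature table.

    Parameters
    ----------
    table : feature table with the predictor columns, target, ``weight``,
        ``network``, ``complete`` and bookkeeping columns (cell_id, hour,
        station_id).
    variant : one of ``aqs``, ``aqs_pa``, ``aqs_pa_smote``.
    forest : hyperparameters (`ForestConfig`).
    smote : SMOTE settings; defaults to `SmoteConfig(seed=forest.seed)` for
        the SMOTE variant and is ignored otherwise.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        variant: str = "aqs_pa",
        forest: ForestConfig = ForestConfig(),
        smote: SmoteConfig | None = None,
        predictors: list[str] | None = None,
        target: str = "pm25",
    ):
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        self.variant = variant
        self.forest_config = forest
        self.predictors = PREDICTORS if predictors is None else list(predictors)
        self.target = target
        self.smote = smote if smote is not None else (
            SmoteConfig(seed=forest.seed) if variant == "aqs_pa_smote" else None
        )

        rows = table
        if "complete" in rows.columns:
            rows = rows[rows["complete"]]
        if "is_synthetic" in rows.columns:
            rows = rows[~rows["is_synthetic"]]
        if variant == "aqs":
            rows = rows[rows["network"] == "AQS"]
        if len(rows) == 0:
            raise ValueError("no complete rows for this variant")
        self.table = rows.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "SmokePM25Model":
        return cls(df, **kw)

    @property
    def exog_names(self) -> list[str]:
        return self.predictors

    def _training_frame(self) -> pd.DataFrame:
        rows = self.table
        if self.variant == "aqs_pa_smote" and self.smote is not None:
            rows = smote_augment(rows, self.smote, predictors=self.predictors, target=self.target)
        return rows

    def fit(self, compute_importance: bool = False) -> "SmokePM25Results":
        train = self._training_frame()
        X = train[self.predictors].to_numpy(float)
        y = train[self.target].to_numpy(float)
        w = train["weight"].to_numpy(float) if "weight" in train.columns else None
        fc = self.forest_config
        forest = WeightedRandomForest(
            n_trees=fc.n_trees,
            m_try=fc.resolve_m_try(len(self.predictors)),
            min_node_size=fc.min_node_size,
            max_depth=fc.max_depth,
            seed=fc.seed,
        ).fit(X, y, sample_weight=w)
        importance = None
        if compute_importance:
            imp = forest.permutation_importance(seed=fc.seed)
            importance = pd.Series(imp, index=self.predictors).sort_values(ascending=False)
        return SmokePM25Results(model=self, forest=forest, training_frame=train, importance=importance)


@dataclass
class SmokePM25Results:
    """Fitted ensemble plus out-of-bag diagnostics.

    For the SMOTE variant the out-of-bag metrics are computed over all
    training rows, synthetic included (cross-validation metrics, by
    contrast, never score synthetic rows).
    """

    model: SmokePM25Model
    forest: WeightedRandomForest
    training_frame: pd.DataFrame
    importance: pd.Series | None = None
    _oob: EvalMetrics | None = field(default=None, repr=False)

    @property
    def oob_predictions(self) -> np.ndarray:
        return self.forest.oob_prediction_

    @property
    def oob_report(self) -> EvalMetrics:
        if self._oob is None:
            y = self.training_frame[self.model.target].to_numpy(float)
            self._oob = evaluate(y, self.oob_predictions)
        return self._oob

    def predict(self, data: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            data = data[self.model.predictors].to_numpy(float)
        return self.forest.predict(data)

    def variable_importance(self) -> pd.Series:
        if self.importance is None:
            imp = self.forest.permutation_importance(seed=self.model.forest_config.seed)
            self.importance = pd.Series(imp, index=self.model.predictors).sort_values(ascending=False)
        return self.importance

    def summary(self) -> str:
        m = self.oob_report
        fc = self.model.forest_config
        lines = [
            "Weighted Random Forest PM2.5 Results",
            "=" * 44,
            f"variant:            {self.model.variant}",
            f"training rows:      {len(self.training_frame)}"
            + (
                f" ({int(self.training_frame['is_synthetic'].sum())} synthetic)"
                if "is_synthetic" in self.training_frame.columns
                else ""
            ),
            f"trees / m_try:      {fc.n_trees} / {fc.resolve_m_try(len(self.model.predictors))}",
            f"min node / depth:   {fc.min_node_size} / {fc.max_depth}",
            "-" * 44,
            f"OOB R2:             {m.r2:.3f}",
            f"OOB RMSE:           {m.rmse:.2f} ug/m3",
            f"slope / intercept:  {m.slope:.3f} / {m.intercept:.2f}",
            f"high-range slope:   {m.high_range_slope:.3f} (n={m.high_range_n})",
        ]
        if self.importance is not None:
            lines.append("-" * 44)
            lines.append("top predictors (OOB permutation importance):")
            for name, val in self.importance.head(5).items():
                lines.append(f"  {name:<22s} {val:9.3f}")
        return "\n".join(lines)
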
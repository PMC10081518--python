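"""Weighted random forest regressor.

Bagged regression trees in which each tree's bootstrap sample is drawn with
selection probability proportional to the observation weight, so a
measurement with weight 0.15 enters the ensemble's training bags about
seven times less often than a fully trusted one. Split search, node-size
and depth limits delegate to scikit-learn trees; out-of-bag predictions
average only the trees whose bootstrap excluded the row.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.tree import DecisionTreeRegressor


class WeightedRandomForest:
    """Regression forest with weight-proportional bootstrap sampling.

    Parameters
    ----------
    n_trees : ensemble size.
    m_try : predictors tried per split; default ceil(sqrt(p)).
    min_node_size : minimum samples in a leaf.
    max_depth : maximum tree depth.
    seed : governs bootstrap draws and per-tree split randomness.
    """

    def __init__(self, n_trees=500, m_try=None, min_node_size=5, max_depth=20, seed=0):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = int(n_trees)
        self.m_try = m_try
        self.min_node_size = int(min_node_size)
        self.max_depth = max_depth
        self.seed = seed
        self.trees_: list[DecisionTreeRegressor] = []
        self.inbag_: np.ndarray | None = None
        self.oob_prediction_: np.ndarray | None = None

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("rows with nulls must be filtered before fitting")
        m_try = self.m_try if self.m_try is not None else math.ceil(math.sqrt(p))
        if not 1 <= m_try <= p:
            raise ValueError(f"m_try={m_try} outside [1, p={p}]")
        if sample_weight is None:
            probs = np.full(n, 1.0 / n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if (w <= 0).any():
                raise ValueError("weights must be in (0, 1]")
            probs = w / w.sum()

        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        inbag = np.zeros((self.n_trees, n), dtype=bool)
        oob_sum = np.zeros(n)
        oob_cnt = np.zeros(n, dtype=int)
        for t in range(self.n_trees):
            idx = rng.choice(n, size=n, replace=True, p=probs)
            tree = DecisionTreeRegressor(
                max_features=m_try,
                min_samples_leaf=self.min_node_size,
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            inbag[t, idx] = True
            oob = ~inbag[t]
            if oob.any():
                oob_sum[oob] += tree.predict(X[oob])
                oob_cnt[oob] += 1
        self.inbag_ = inbag
        with np.errstate(invalid="ignore"):
            self.oob_prediction_ = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
        self._fit_X, self._fit_y = X, y
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)

    def permutation_importance(self, n_repeats: int = 1, seed: int = 0) -> np.ndarray:
        """OOB permutation importance: mean increase in OOB MSE when one
        predictor is shuffled (ensemble-level, computed on OOB predictions)."""
        if self.inbag_ is None:
            raise RuntimeError("fit first")
        X, y = self._fit_X, self._fit_y
        rng = np.random.default_rng(seed)
        base = self._oob_mse(X, y)
        p = X.shape[1]
        imp = np.zeros(p)
        for j in range(p):
            vals = 0.0
            for _ in range(n_repeats):
                Xp = X.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                vals += self._oob_mse(Xp, y) - base
            imp[j] = vals / n_repeats
        return imp

    def _oob_mse(self, X, y) -> float:
        oob_sum = np.zeros(len(X))
        oob_cnt = np.zeros(len(X), dtype=int)
        for t, tree in enumerate(self.trees_):
            oob = ~self.inbag_[t]
            if oob.any():
                oob_sum[oob] += tree.predict(X[oob])
                oob_cnt[oob] += 1
        ok = oob_cnt > 0
        pred = oob_sum[ok] / oob_cnt[ok]
        return float(np.mean((pred - y[ok]) ** 2))
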
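"""SMOTE for the continuous, weighted PM2.5 target.

High-concentration observations (at or above 100 μg/m³, roughly the rare
smoke-impacted 2% of the data) form the minority class. For each minority
row, synthetic rows are drawn by linear interpolation toward one of its k
nearest minority neighbors in standardized continuous-predictor space:

    x_syn = x_seed + g · (x_neighbor − x_seed),   g ~ Uniform(0, 1),

with the target interpolated alongside, binary predictors copied from the
seed, and the seed's observation weight (and bookkeeping columns) inherited.
Applied to training data only; the count law |out| = |in| + n_synth·|minority|
holds exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .features import BINARY_PREDICTORS, PREDICTORS

logger = logging.getLogger(__name__)

MINORITY_CUTOFF = 100.0


@dataclass(frozen=True)
class SmoteConfig:
    minority_cutoff: float = MINORITY_CUTOFF
    n_synth_per_minority: int = 2
    k_neighbors: int = 5
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if self.minority_cutoff <= 0:
            raise ValueError("minority_cutoff must be > 0")
        if self.n_synth_per_minority < 0:
            raise ValueError("n_synth_per_minority must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def label_minority(target, cutoff: float = MINORITY_CUTOFF) -> np.ndarray:
    """True iff target >= cutoff (the cutoff itself is minority)."""
    return np.asarray(target, dtype=float) >= cutoff


def minority_share_after(n_rows: int, n_minority: int, n_synth: int) -> float:
    """Post-augmentation minority fraction (1+n)·m / (N + n·m)."""
    return (1 + n_synth) * n_minority / (n_rows + n_synth * n_minority)


def _row_keys(df: pd.DataFrame) -> np.ndarray:
    """Stable per-row RNG keys: (cell_id, hour) when available so the draw
    stream follows the observation, positional index otherwise."""
    if "cell_id" in df.columns and "hour" in df.columns:
        return (
            df["cell_id"].to_numpy(np.int64) * 100_000 + df["hour"].to_numpy(np.int64)
        ) % (2**31)
    return np.arange(len(df), dtype=np.int64)


def smote_augment(
    rows: pd.DataFrame,
    config: SmoteConfig,
    predictors: list[str] | None = None,
    binary: list[str] | None = None,
    target: str = "pm25",
) -> pd.DataFrame:
    """Augment a training table with synthetic minority rows.

    Returns the input rows (``is_synthetic`` False) followed by the
    synthetic rows in minority-key order. Majority rows are untouched. With
    no minority rows the input is returned unchanged (warning logged); with
    fewer than k+1 minority rows the neighbor count shrinks to what exists.
    """
    predictors = PREDICTORS if predictors is None else predictors
    binary = BINARY_PREDICTORS if binary is None else binary
    continuous = [c for c in predictors if c not in binary] + [target]

    out = rows.copy()
    if "is_synthetic" not in out.columns:
        out["is_synthetic"] = False
    minority_mask = label_minority(out[target], config.minority_cutoff)
    m = int(minority_mask.sum())
    if m == 0:
        logger.warning("no minority rows at cutoff %.1f; returning input unchanged", config.minority_cutoff)
        return out.reset_index(drop=True)
    if config.n_synth_per_minority == 0:
        return out.reset_index(drop=True)

    minority = out[minority_mask].reset_index(drop=True)
    keys = _row_keys(minority)
    order = np.argsort(keys, kind="stable")
    minority = minority.iloc[order].reset_index(drop=True)
    keys = keys[order]

    X = minority[continuous].to_numpy(float)
    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
    else:
        Z = X

    k = min(config.k_neighbors, m - 1)
    if k < config.k_neighbors:
        logger.info("only %d minority rows; k shrunk to %d", m, max(k, 0))
    if k >= 1:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
        _, nbr = nn.kneighbors(Z)
        nbr = nbr[:, 1:]  # drop self
    else:
        nbr = np.zeros((m, 1), dtype=int)  # single minority row: itself

    n_synth = config.n_synth_per_minority
    js = np.empty((m, n_synth), dtype=int)
    gs = np.empty((m, n_synth))
    for i in range(m):
        rng = np.random.default_rng([config.seed, int(keys[i])])
        for s in range(n_synth):
            js[i, s] = nbr[i, int(rng.integers(nbr.shape[1]))]
            gs[i, s] = rng.random()

    seed_idx = np.repeat(np.arange(m), n_synth)
    j_flat = js.ravel()
    g_flat = gs.ravel()
    synth = minority.iloc[seed_idx].reset_index(drop=True)
    synth[continuous] = X[seed_idx] + g_flat[:, None] * (X[j_flat] - X[seed_idx])
    synth["is_synthetic"] = True
    return pd.concat([out, synth], ignore_index=True)
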
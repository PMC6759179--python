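"""Scaling, ranking and ensemble combination of run weight columns.

Raw weights live on incompatible scales across runs (log-likelihood ratios,
normalised scores in [0, 1], agreement counts), so cross-run comparison uses
two devices: min-max scaling of each column to [0, 1],

    scaled = (W - min W) / (max W - min W),

and dense ranking from the highest weight (rank 1) downward, where tied
weights share a rank and ranks advance by one per distinct value.  Two
ensemble combinations are provided: the per-pair arithmetic mean of scaled
weights across all runs, and rank-1-or-2 vote counting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def scale_weights(column) -> np.ndarray:
    """Min-max scale a weight column to [0, 1].

    The minimum maps to 0 and the maximum to 1.  A constant column is mapped
    to all zeros and flagged in the log.  NaN entries (pairs a truncated run
    never reported) stay NaN.  Empty input is rejected.
    """
    w = np.asarray(column, dtype=float)
    if w.size == 0:
        raise ValueError("cannot scale an empty weight column")
    lo, hi = np.nanmin(w), np.nanmax(w)
    if np.isnan(lo):
        raise ValueError("cannot scale an all-NaN weight column")
    if hi == lo:
        log.warning("scale_weights: constant column; all scaled weights set to 0")
        out = np.zeros_like(w)
        out[np.isnan(w)] = np.nan
        return out
    return (w - lo) / (hi - lo)


def rank_weights(column) -> np.ndarray:
    """Dense ranks, 1 = highest weight; tied weights share a rank.

    NaN entries receive NaN ranks (a truncated run assigned them no weight).
    """
    s = pd.Series(np.asarray(column, dtype=float))
    if s.size == 0:
        raise ValueError("cannot rank an empty weight column")
    return s.rank(method="dense", ascending=False).to_numpy()


def ensemble_average(scaled: pd.DataFrame) -> np.ndarray:
    """Per-pair arithmetic mean of scaled weights across runs.

    All columns must cover the same pair set; a pair absent from a
    positive-only run (NaN) contributes that run's scaled minimum, 0.  The
    divisor is always the number of runs.
    """
    if scaled.isna().any().any():
        n = int(scaled.isna().any(axis=1).sum())
        log.info(
            "ensemble_average: %d pairs missing from truncated runs imputed at 0", n
        )
    filled = scaled.fillna(0.0)
    return filled.mean(axis=1).to_numpy()


def ensemble_vote(ranks: pd.DataFrame, k: int = 2) -> np.ndarray:
    """Votes per pair: the number of runs ranking the pair in the top ``k``.

    With the default k = 2 this is "rank 1 or 2" voting.  Unranked (NaN)
    entries never vote.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return (ranks <= k).sum(axis=1).to_numpy()
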
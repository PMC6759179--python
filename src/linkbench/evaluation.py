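"""Gold-standard evaluation of linkage runs.

The benchmark's reference label is MRN agreement: a candidate pair counts as
a gold match iff both records carry a non-missing, equal medical record
number (a missing MRN therefore counts as a non-match, exactly how an
enterprise MRN check behaves).  Because MRN assignment itself has a small
error rate, the gold standard is *alloyed*; on synthetic data the latent
true-person identity is also available, letting the discrepancy between gold
labels and truth be measured directly.

Machinery provided per run: confusion counts and the four standard test
characteristics at rank-based operating points, ROC curves and AUC over
weights, cross-run weight correlation and principal components, and the
descriptive weight summaries (distinct-weight count, extremes, pair counts at
the two highest/lowest weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

log = logging.getLogger(__name__)


def gold_labels(pairs: pd.DataFrame, ipd: pd.DataFrame, opd: pd.DataFrame) -> np.ndarray:
    """1 iff both records' MRNs are present and equal, else 0."""
    a = ipd.set_index("record_id")["mrn"].reindex(pairs["ipd_record_id"]).to_numpy(object)
    b = opd.set_index("record_id")["mrn"].reindex(pairs["opd_record_id"]).to_numpy(object)
    ok = pd.notna(a) & pd.notna(b)
    return (ok & (a == b)).astype(int)


def truth_labels(pairs: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """1 iff both records map to the same latent person (synthetic oracle)."""
    lookup = truth.set_index("record_id")["true_person_id"]
    a = lookup.reindex(pairs["ipd_record_id"]).to_numpy(object)
    b = lookup.reindex(pairs["opd_record_id"]).to_numpy(object)
    return (pd.notna(a) & pd.notna(b) & (a == b)).astype(int)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")


def confusion_at_rank(ranks, labels, max_rank: int = 1) -> ConfusionCounts:
    """Declare pairs with rank <= ``max_rank`` as matches and score them.

    Ranks are dense, 1 = highest weight; NaN ranks (pairs a truncated run
    never weighted) are never declared.
    """
    r = np.asarray(ranks, dtype=float)
    y = np.asarray(labels, dtype=int)
    declared = r <= max_rank  # NaN compares False
    return ConfusionCounts(
        tp=int((declared & (y == 1)).sum()),
        fp=int((declared & (y == 0)).sum()),
        tn=int((~declared & (y == 0)).sum()),
        fn=int((~declared & (y == 1)).sum()),
    )


def roc_auc(weights, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (one operating point per distinct weight) and trapezoidal AUC.

    Equivalent to the Mann-Whitney statistic with the 1/2 tie convention.
    Pairs with NaN weights are placed below every threshold (never declared).
    Requires both label classes to be present.
    """
    w = np.asarray(weights, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs at least one pair of each class")
    if np.isnan(w).any():
        lo = np.nanmin(w)
        w = np.where(np.isnan(w), lo - 1.0, w)
    fpr, tpr, _ = _roc_curve(y, w)
    return fpr, tpr, float(_auc(fpr, tpr))


def weight_correlations(weights: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between run weight columns."""
    if weights.shape[1] < 2:
        raise ValueError("need at least two runs to correlate")
    return weights.corr(method="pearson")


def weight_pca(weights: pd.DataFrame) -> np.ndarray:
    """Explained-variance ratios of the weight correlation matrix.

    Eigendecomposition of the run-by-run correlation matrix; ratios are
    non-increasing and sum to 1.  Zero-variance columns are dropped (flagged).
    """
    variable = weights.std(ddof=0) > 0
    if not variable.all():
        log.warning("weight_pca: %d constant columns dropped", (~variable).sum())
    corr = weights.loc[:, variable].corr().to_numpy()
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvals / eigvals.sum()


def summarize_run(column) -> dict:
    """Descriptive weight summary for one run.

    Distinct-weight count, min and max, and the pair counts at the two
    highest and two lowest distinct weights (None where fewer than two
    distinct weights exist).  NaN entries (truncated pairs) are excluded.
    """
    w = np.asarray(column, dtype=float)
    w = w[~np.isnan(w)]
    if w.size == 0:
        raise ValueError("cannot summarize an empty weight column")
    values, counts = np.unique(w, return_counts=True)
    k = len(values)
    return {
        "n_distinct_weights": int(k),
        "min_weight": float(values[0]),
        "max_weight": float(values[-1]),
        "pairs_at_highest": int(counts[-1]),
        "pairs_at_second_highest": int(counts[-2]) if k > 1 else None,
        "pairs_at_lowest": int(counts[0]),
        "pairs_at_second_lowest": int(counts[1]) if k > 1 else None,
    }
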
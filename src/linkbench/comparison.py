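"""Blocked candidate-pair generation and per-field comparison outcomes.

Comparing every inpatient row against every outpatient row is quadratic and
pointless; *blocking* restricts candidate pairs to those agreeing exactly on
a highly reliable key — here date of birth or year of birth.  For each
blocked pair the three matching variables (first name, last name, gender) are
compared either exactly (agree / disagree / missing, capitalization counts)
or by Jaro-Winkler similarity for the name fields.  Gender, a one-character
field, is always compared exactly: a string-similarity score between "F" and
"M" carries no information.

Comparison outcomes are stored numerically: 1.0 agree, 0.0 disagree, NaN
missing; inexact name outcomes are similarities in [0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MATCH_FIELDS = ("first_name", "last_name", "gender")
BLOCK_VARS = ("dob", "yob")

AGREE, DISAGREE, MISSING = "agree", "disagree", "missing"


def block_pairs(
    ipd: pd.DataFrame, opd: pd.DataFrame, block_var: str = "dob"
) -> pd.DataFrame:
    """All cross-source pairs agreeing exactly on a non-missing block value.

    Returns a DataFrame with columns ``ipd_record_id``/``opd_record_id``; the
    pair count equals sum over block values v of n_IPD(v) * n_OPD(v).  Rows
    with a missing block value on either side cannot agree on the block and
    are excluded (their count is logged).
    """
    if block_var not in BLOCK_VARS:
        raise ValueError(
            f"unknown blocking variable {block_var!r}; expected one of {BLOCK_VARS}"
        )
    left = ipd[["record_id", block_var]].dropna(subset=[block_var])
    right = opd[["record_id", block_var]].dropna(subset=[block_var])
    n_miss = (len(ipd) - len(left)) + (len(opd) - len(right))
    if n_miss:
        log.info("block_pairs: %d records excluded for missing %s", n_miss, block_var)
    pairs = left.merge(right, on=block_var, suffixes=("_ipd", "_opd"))
    pairs = pairs.rename(
        columns={"record_id_ipd": "ipd_record_id", "record_id_opd": "opd_record_id"}
    )[["ipd_record_id", "opd_record_id"]]
    log.info("block_pairs: %d candidate pairs on %s", len(pairs), block_var)
    return pairs.reset_index(drop=True)


def compare_exact(a, b) -> str:
    """Trichotomous exact comparison: byte-identical strings agree."""
    if _is_missing(a) or _is_missing(b):
        return MISSING
    return AGREE if a == b else DISAGREE


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def jaro(s1: str, s2: str) -> float:
    """Jaro similarity: common characters within a sliding window, penalised
    for transpositions.

    With m common characters (within window floor(max(len)/2) - 1) and t half
    the number of transposed common characters:

        J = (m/|s1| + m/|s2| + (m - t)/m) / 3

    0 when no characters are common; 1 iff the strings are identical.  Empty
    input on either side yields 0 by convention.
    """
    if _is_missing(s1) or _is_missing(s2):
        raise ValueError("jaro requires non-missing inputs")
    if len(s1) == 0 or len(s2) == 0:
        log.debug("jaro: empty string compared, similarity 0 by convention")
        return 0.0
    if s1 == s2:
        return 1.0
    window = max(len(s1), len(s2)) // 2 - 1
    window = max(window, 0)
    used2 = [False] * len(s2)
    common1 = []
    for i, c in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len(s2), i + window + 1)
        for j in range(lo, hi):
            if not used2[j] and s2[j] == c:
                used2[j] = True
                common1.append((i, j))
                break
    m = len(common1)
    if m == 0:
        return 0.0
    # transpositions: matched characters out of mutual order, halved with
    # truncation (the canonical strcmp95 convention)
    s1_matched = [s1[i] for i, _ in common1]
    s2_matched = [s2[j] for j in sorted(j for _, j in common1)]
    t = sum(c1 != c2 for c1, c2 in zip(s1_matched, s2_matched)) // 2
    return (m / len(s1) + m / len(s2) + (m - t) / m) / 3.0


def jaro_winkler(
    s1: str,
    s2: str,
    prefix_scale: float = 0.1,
    max_prefix: int = 4,
    boost_threshold: float = 0.0,
) -> float:
    """Jaro similarity with Winkler's common-prefix bonus.

    JW = J + l * p * (1 - J), with l the common-prefix length capped at
    ``max_prefix`` and p = ``prefix_scale`` (must lie in [0, 0.25] so the
    result stays in [0, 1]).  The bonus applies whenever J exceeds
    ``boost_threshold``; the default 0 applies it unconditionally, the most
    common dialect.
    """
    if not 0.0 <= prefix_scale <= 0.25:
        raise ValueError(
            f"prefix_scale must lie in [0, 0.25], got {prefix_scale}"
        )
    j = jaro(s1, s2)
    if j <= boost_threshold:
        return j
    ell = 0
    for c1, c2 in zip(s1[:max_prefix], s2[:max_prefix]):
        if c1 != c2:
            break
        ell += 1
    return j + ell * prefix_scale * (1.0 - j)


def _exact_outcome_column(a: pd.Series, b: pd.Series) -> np.ndarray:
    out = np.where(a.to_numpy(object) == b.to_numpy(object), 1.0, 0.0)
    out[a.isna().to_numpy() | b.isna().to_numpy()] = np.nan
    return out


def _similarity_column(a: pd.Series, b: pd.Series, **jw_kwargs) -> np.ndarray:
    """Vectorised Jaro-Winkler with memoisation over distinct value pairs."""
    av = a.to_numpy(object)
    bv = b.to_numpy(object)
    out = np.full(len(av), np.nan)
    cache: dict[tuple, float] = {}
    for i in range(len(av)):
        x, y = av[i], bv[i]
        if _is_missing(x) or _is_missing(y):
            continue
        key = (x, y)
        s = cache.get(key)
        if s is None:
            s = jaro_winkler(x, y, **jw_kwargs)
            cache[key] = s
        out[i] = s
    return out


def build_comparison_vectors(
    pairs: pd.DataFrame,
    ipd: pd.DataFrame,
    opd: pd.DataFrame,
    fields=MATCH_FIELDS,
    mode: str = "exact",
    **jw_kwargs,
) -> pd.DataFrame:
    """Per-pair comparison outcomes for the matching variables.

    ``mode='exact'``: every field is the 1/0/NaN trichotomy.
    ``mode='inexact'``: name fields carry Jaro-Winkler similarities; gender
    stays trichotomous.
    """
    if mode not in ("exact", "inexact"):
        raise ValueError(f"mode must be 'exact' or 'inexact', got {mode!r}")
    li = ipd.set_index("record_id").loc[pairs["ipd_record_id"]]
    ro = opd.set_index("record_id").loc[pairs["opd_record_id"]]
    out = pairs[["ipd_record_id", "opd_record_id"]].copy()
    for f in fields:
        a = li[f].reset_index(drop=True)
        b = ro[f].reset_index(drop=True)
        if mode == "exact" or f == "gender":
            out[f] = _exact_outcome_column(a, b)
        else:
            out[f] = _similarity_column(a, b, **jw_kwargs)
    return out
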
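"""Independent reference implementations used only as test oracles.

Each function here is written from the textbook definition, deliberately not
sharing code (or algorithmic structure, where feasible) with the package.
"""

from __future__ import annotations

import numpy as np


def osa_distance(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Substitutions, insertions, deletions and adjacent transpositions each
    cost 1; full dynamic program, no shortcuts.
    """
    la, lb = len(a), len(b)
    d = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        d[i][0] = i
    for j in range(lb + 1):
        d[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + cost,
            )
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d[i][j] = min(d[i][j], d[i - 2][j - 2] + 1)
    return d[la][lb]


def levenshtein(a: str, b: str) -> int:
    """Plain Levenshtein distance (no transposition)."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[lb]


def ref_jaro(s1: str, s2: str) -> float:
    """Reference Jaro similarity via explicit match-flag arrays."""
    if len(s1) == 0 or len(s2) == 0:
        return 0.0
    if s1 == s2:
        return 1.0
    match_window = max(len(s1), len(s2)) // 2 - 1
    flags1 = [False] * len(s1)
    flags2 = [False] * len(s2)
    m = 0
    for i in range(len(s1)):
        start = max(0, i - match_window)
        end = min(i + match_window + 1, len(s2))
        for j in range(start, end):
            if not flags2[j] and s2[j] == s1[i]:
                flags1[i] = flags2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    k = t = 0
    for i in range(len(s1)):
        if flags1[i]:
            while not flags2[k]:
                k += 1
            if s1[i] != s2[k]:
                t += 1
            k += 1
    t //= 2
    return (m / len(s1) + m / len(s2) + (m - t) / m) / 3.0


def ref_jaro_winkler(s1: str, s2: str, p: float = 0.1, max_l: int = 4) -> float:
    j = ref_jaro(s1, s2)
    ell = 0
    for a, b in zip(s1, s2):
        if a != b or ell == max_l:
            break
        ell += 1
    ell = min(ell, max_l)
    return j + ell * p * (1 - j)


def fs_weight_brute(pattern, m, u, missing_policy="zero_contribution"):
    """Hand-summed Fellegi-Sunter weight over one trichotomous pattern.

    ``pattern`` is a sequence over {"agree", "disagree", "missing"}.
    """
    total = 0.0
    for outcome, mi, ui in zip(pattern, m, u):
        if outcome == "agree":
            total += np.log2(mi / ui)
        elif outcome == "disagree":
            total += np.log2((1 - mi) / (1 - ui))
        elif outcome == "missing":
            if missing_policy == "as_disagreement":
                total += np.log2((1 - mi) / (1 - ui))
            elif missing_policy == "zero_contribution":
                total += 0.0
            else:
                raise ValueError(missing_policy)
        else:
            raise ValueError(outcome)
    return total


def mann_whitney_auc(weights, labels) -> float:
    """AUC as the Mann-Whitney probability, ties counted 1/2, O(n^2)."""
    w = np.asarray(weights, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = w[y == 1]
    neg = w[y == 0]
    total = 0.0
    for wp in pos:
        for wn in neg:
            if wp > wn:
                total += 1.0
            elif wp == wn:
                total += 0.5
    return total / (len(pos) * len(neg))
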
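"""Pair-weight computation under four weight-determination families.

Every linkage run turns per-field comparison outcomes into one numeric weight
per candidate pair.  Four families are implemented:

* **Fellegi-Sunter (FS)** — the sum over fields of log2 likelihood ratios:
  log2(m/u) on agreement, log2((1-m)/(1-u)) on disagreement, where the
  M-probability m is P(field agrees | pair is a true match) and the
  U-probability u is P(field agrees | pair is a non-match).  m and u are
  supplied exogenously (defaults: m = 0.95, u = 1/#distinct values).
* **EM** — the same weight formula, but (m, u, match prevalence p) are
  estimated endogenously by expectation-maximization on a two-class
  conditional-independence mixture over binary agreement vectors.
* **EpiLink** — a normalised similarity-weighted score in [0, 1]:
  sum(s_i * w_i) / sum(w_i) with field weights w_i = log2((1-e_i)/f_i) from
  per-field error rates e_i and average value frequencies f_i; missing fields
  drop out of numerator and denominator.
* **Deterministic** — the count of agreeing fields (0..3 for three matching
  variables); a fractional variant sums similarities directly.

Real software packages disagree on dialect details — how missing values are
scored, and how a string similarity is converted into an agreement weight.
:class:`RunProfile` captures those dialect switches, and
:func:`default_run_matrix` enumerates the 17 named algorithm/dialect
combinations that make up the benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from linkbench.comparison import MATCH_FIELDS

log = logging.getLogger(__name__)

_EPS = 1e-6

#: missing-value policies for FS/EM/deterministic scoring
ZERO_CONTRIBUTION = "zero_contribution"  # missing field contributes weight 0
AS_DISAGREEMENT = "as_disagreement"  # missing field scored as a disagreement

#: similarity-to-weight conversion dialects for inexact runs
THRESHOLD_BINARY = "threshold_binary"  # s >= threshold counts as agreement
INTERPOLATE = "interpolate"  # w = s*w_agree + (1-s)*w_disagree


@dataclass(frozen=True)
class MatchParams:
    """Per-field M-/U-probabilities plus the match prevalence p."""

    m: dict[str, float]
    u: dict[str, float]
    p: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"match prevalence p must lie in (0,1), got {self.p}")
        for f in self.m:
            m, u = self.m[f], self.u[f]
            if not 0.0 < u < m < 1.0:
                raise ValueError(
                    f"field {f!r}: need 0 < u < m < 1 for an informative field, "
                    f"got m={m}, u={u}"
                )

    @property
    def fields(self) -> list[str]:
        return list(self.m)


@dataclass(frozen=True)
class EpiLinkParams:
    """Per-field error rates e and average value frequencies f.

    The field weight is w = log2((1-e)/f); parameters must make every field
    informative (w > 0).
    """

    e: dict[str, float]
    f: dict[str, float]

    def __post_init__(self) -> None:
        for name in self.e:
            e, f = self.e[name], self.f[name]
            if not (0.0 < e < 1.0 and 0.0 < f < 1.0):
                raise ValueError(f"field {name!r}: e and f must lie in (0,1)")
            if np.log2((1.0 - e) / f) <= 0:
                raise ValueError(
                    f"field {name!r}: weight log2((1-e)/f) must be positive"
                )

    @property
    def weights(self) -> dict[str, float]:
        return {k: float(np.log2((1.0 - self.e[k]) / self.f[k])) for k in self.e}

    @classmethod
    def from_match_params(cls, params: MatchParams) -> "EpiLinkParams":
        """e = 1 - m, f = u: one parameter vocabulary for the whole matrix."""
        return cls(
            e={k: 1.0 - v for k, v in params.m.items()},
            f=dict(params.u),
        )


@dataclass(frozen=True)
class RunProfile:
    """One named algorithm/dialect combination of the benchmark matrix."""

    name: str
    string_mode: str  # "exact" | "inexact"
    method: str  # "FS" | "EM" | "EPI" | "DET"
    missing_policy: str = ZERO_CONTRIBUTION
    inexact_conversion: str = THRESHOLD_BINARY
    similarity_threshold: float = 0.95
    positive_only_output: bool = False

    def __post_init__(self) -> None:
        if self.string_mode not in ("exact", "inexact"):
            raise ValueError(f"bad string_mode {self.string_mode!r}")
        if self.method not in ("FS", "EM", "EPI", "DET"):
            raise ValueError(f"bad method {self.method!r}")
        if self.missing_policy not in (ZERO_CONTRIBUTION, AS_DISAGREEMENT):
            raise ValueError(f"bad missing_policy {self.missing_policy!r}")
        if self.inexact_conversion not in (THRESHOLD_BINARY, INTERPOLATE):
            raise ValueError(f"bad inexact_conversion {self.inexact_conversion!r}")
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must lie in [0,1]")
        if self.method == "EPI" and self.missing_policy != ZERO_CONTRIBUTION:
            raise ValueError(
                "EpiLink drops missing fields; only zero_contribution is coherent"
            )


def default_match_params(
    dataset: pd.DataFrame,
    fields=MATCH_FIELDS,
    m: float = 0.95,
    n_pairs: int | None = None,
    expected_matches: int | None = None,
) -> MatchParams:
    """Package-default parameters: m = 0.95, u = 1/#distinct field values.

    u for each field is the reciprocal of the number of distinct non-missing
    values observed in the designated dataset (the chance two unrelated
    records agree if values were uniform).  A field with a single distinct
    value would get u = 1 and carry no information; it is rejected.
    """
    if dataset.empty:
        raise ValueError("cannot derive match parameters from an empty dataset")
    u = {}
    for f in fields:
        k = int(dataset[f].dropna().nunique())
        if k <= 1:
            raise ValueError(
                f"field {f!r} has {k} distinct value(s); u would be 1 and the "
                "field uninformative — drop it from the matching variables"
            )
        u[f] = 1.0 / k
    if n_pairs and expected_matches:
        p = min(max(expected_matches / n_pairs, _EPS), 1 - _EPS)
    else:
        p = 0.01
    return MatchParams(m={f: m for f in fields}, u=u, p=p)


# ---------------------------------------------------------------------------
# Fellegi-Sunter


def _field_weights(params: MatchParams, f: str) -> tuple[float, float]:
    aw = float(np.log2(params.m[f] / params.u[f]))
    dw = float(np.log2((1.0 - params.m[f]) / (1.0 - params.u[f])))
    return aw, dw


def fs_weight(
    vectors: pd.DataFrame,
    params: MatchParams,
    profile: RunProfile | None = None,
) -> np.ndarray:
    """Fellegi-Sunter weight W = sum of per-field log2 likelihood ratios.

    Exact mode: agreement contributes log2(m/u), disagreement
    log2((1-m)/(1-u)), missing contributes 0 (``zero_contribution``) or the
    disagreement weight (``as_disagreement``).  Inexact mode first converts
    the similarity per the profile dialect: ``threshold_binary`` binarizes at
    the profile threshold; ``interpolate`` blends the two weights linearly,
    w = s*log2(m/u) + (1-s)*log2((1-m)/(1-u)).
    """
    profile = profile or RunProfile("adhoc/FS", "exact", "FS")
    total = np.zeros(len(vectors))
    for f in params.fields:
        aw, dw = _field_weights(params, f)
        s = vectors[f].to_numpy(float)
        if np.nanmin(s, initial=0.0) < 0 or np.nanmax(s, initial=0.0) > 1:
            raise ValueError(f"field {f!r}: similarities must lie in [0, 1]")
        if profile.string_mode == "inexact" and f != "gender":
            if profile.inexact_conversion == THRESHOLD_BINARY:
                s = np.where(np.isnan(s), np.nan, (s >= profile.similarity_threshold).astype(float))
                contrib = np.where(s == 1.0, aw, dw)
            else:
                contrib = s * aw + (1.0 - s) * dw
        else:
            contrib = np.where(s == 1.0, aw, dw)
        miss = np.isnan(s)
        if profile.missing_policy == ZERO_CONTRIBUTION:
            contrib = np.where(miss, 0.0, contrib)
        else:
            contrib = np.where(miss, dw, contrib)
        total += contrib
    return total


# ---------------------------------------------------------------------------
# EM estimation


@dataclass
class EMResult:
    params: MatchParams
    converged: bool
    degenerate: bool
    log_likelihood: float
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)


def em_posterior(vectors: pd.DataFrame, params: MatchParams) -> np.ndarray:
    """E-step: posterior match probability per comparison vector.

    g = p * prod_i m_i^g_i (1-m_i)^(1-g_i) / [same + (1-p) * prod over u].
    NaN fields are excluded from the products.
    """
    fields = params.fields
    g1 = vectors[fields].to_numpy(float)
    observed = ~np.isnan(g1)
    g1 = np.nan_to_num(g1)
    m = np.array([params.m[f] for f in fields])
    u = np.array([params.u[f] for f in fields])
    logm = np.where(observed, g1 * np.log(m) + (1 - g1) * np.log(1 - m), 0.0).sum(axis=1)
    logu = np.where(observed, g1 * np.log(u) + (1 - g1) * np.log(1 - u), 0.0).sum(axis=1)
    a = np.log(params.p) + logm
    b = np.log(1 - params.p) + logu
    hi = np.maximum(a, b)
    return np.exp(a - (hi + np.log(np.exp(a - hi) + np.exp(b - hi))))


def em_estimate(
    vectors: pd.DataFrame,
    init: MatchParams,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EMResult:
    """Fit the two-class conditional-independence mixture by EM.

    ``vectors`` holds binary agreement indicators (1/0) with NaN for missing;
    missing fields are excluded from a vector's likelihood and from that
    field's M-step counts (callers wanting missing-as-disagreement pre-fill
    NaN with 0).  Vectors are collapsed to distinct patterns first, so the
    cost per iteration is O(#patterns * #fields) regardless of pair count.

    E-step: posterior match probability per pattern,
        g = p * prod_i m_i^g_i (1-m_i)^(1-g_i) / (same + (1-p) * prod_i ...u...).
    M-step: p, m_i, u_i re-estimated as posterior-weighted frequencies.
    Estimates are clamped to [1e-6, 1 - 1e-6]; the log-likelihood is
    non-decreasing across iterations.
    """
    fields = init.fields
    coded = vectors[fields].fillna(-1.0).to_numpy(float)
    patterns, counts = np.unique(coded, axis=0, return_counts=True)
    if len(patterns) < 2:
        log.warning("em_estimate: single agreement pattern observed; degenerate")
        return EMResult(init, False, True, float("-inf"), 0)

    gamma = patterns  # (K, F): 1 agree, 0 disagree, -1 missing
    observed = gamma >= 0
    g1 = np.where(observed, gamma, 0.0)

    m = np.array([init.m[f] for f in fields])
    u = np.array([init.u[f] for f in fields])
    p = init.p
    degenerate = False
    trace: list[float] = []
    loglik = -np.inf
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        logm = np.where(observed, g1 * np.log(m) + (1 - g1) * np.log(1 - m), 0.0).sum(axis=1)
        logu = np.where(observed, g1 * np.log(u) + (1 - g1) * np.log(1 - u), 0.0).sum(axis=1)
        a = np.log(p) + logm
        b = np.log(1 - p) + logu
        hi = np.maximum(a, b)
        log_mix = hi + np.log(np.exp(a - hi) + np.exp(b - hi))
        new_loglik = float((counts * log_mix).sum())
        g = np.exp(a - log_mix)

        wm = counts * g
        wu = counts * (1.0 - g)
        new_p = wm.sum() / counts.sum()
        with np.errstate(invalid="ignore"):
            new_m = (wm[:, None] * g1 * observed).sum(axis=0) / (
                wm[:, None] * observed
            ).sum(axis=0)
            new_u = (wu[:, None] * g1 * observed).sum(axis=0) / (
                wu[:, None] * observed
            ).sum(axis=0)
        clipped_m = np.clip(np.nan_to_num(new_m, nan=0.5), _EPS, 1 - _EPS)
        clipped_u = np.clip(np.nan_to_num(new_u, nan=0.5), _EPS, 1 - _EPS)
        if (clipped_m != new_m).any() or (clipped_u != new_u).any():
            degenerate = True
        new_p = float(np.clip(new_p, _EPS, 1 - _EPS))

        delta = max(
            np.abs(clipped_m - m).max(),
            np.abs(clipped_u - u).max(),
            abs(new_p - p),
        )
        m, u, p = clipped_m, clipped_u, new_p
        trace.append(new_loglik)
        loglik = new_loglik
        if delta < tol:
            converged = True
            break

    if not converged:
        log.warning("em_estimate: no convergence in %d iterations", max_iter)
    if degenerate:
        log.warning("em_estimate: estimates clamped away from {0,1}")

    # keep the u < m ordering MatchParams requires; EM label-switching can
    # flip the two classes, in which case swap them back
    if (u >= m).all():
        m, u, p = u, m, 1.0 - p
        log.info("em_estimate: classes swapped to restore m > u")
    u = np.clip(np.minimum(u, m - 1e-9), 1e-12, None)
    params = MatchParams(
        m={f: float(v) for f, v in zip(fields, m)},
        u={f: float(v) for f, v in zip(fields, u)},
        p=float(p),
    )
    return EMResult(params, converged, degenerate, loglik, n_iter, trace)


def binarize_vectors(vectors: pd.DataFrame, profile: RunProfile,
                     fields=MATCH_FIELDS) -> pd.DataFrame:
    """Agreement indicators for EM under the profile's dialect.

    Inexact name similarities binarize at the profile threshold; missing
    becomes 0 under ``as_disagreement`` and stays NaN (excluded) under
    ``zero_contribution``.
    """
    out = vectors[["ipd_record_id", "opd_record_id"]].copy() if "ipd_record_id" in vectors else pd.DataFrame(index=vectors.index)
    for f in fields:
        s = vectors[f].to_numpy(float)
        if profile.string_mode == "inexact" and f != "gender":
            b = np.where(np.isnan(s), np.nan, (s >= profile.similarity_threshold).astype(float))
        else:
            b = np.where(np.isnan(s), np.nan, (s == 1.0).astype(float))
        if profile.missing_policy == AS_DISAGREEMENT:
            b = np.nan_to_num(b, nan=0.0)
        out[f] = b
    return out


# ---------------------------------------------------------------------------
# EpiLink


def epilink_weight(vectors: pd.DataFrame, params: EpiLinkParams) -> np.ndarray:
    """Normalised EpiLink score in [0, 1].

    W = sum_i s_i * w_i / sum_i w_i over the non-missing fields, with
    w_i = log2((1-e_i)/f_i).  Full agreement scores exactly 1, full
    disagreement exactly 0.  Pairs with every field missing get NaN and are
    flagged.
    """
    w = params.weights
    num = np.zeros(len(vectors))
    den = np.zeros(len(vectors))
    for f, wf in w.items():
        s = vectors[f].to_numpy(float)
        obs = ~np.isnan(s)
        num += np.where(obs, np.nan_to_num(s) * wf, 0.0)
        den += np.where(obs, wf, 0.0)
    out = np.full(len(vectors), np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if (~ok).any():
        log.warning("epilink_weight: %d pairs with all fields missing", (~ok).sum())
    return out


# ---------------------------------------------------------------------------
# deterministic


def deterministic_weight(
    vectors: pd.DataFrame,
    profile: RunProfile | None = None,
    fields=MATCH_FIELDS,
) -> np.ndarray:
    """Count of agreeing fields (missing never counts as agreement).

    Exact mode yields integers 0..#fields.  Inexact mode follows the
    profile's conversion dialect: ``threshold_binary`` counts similarities at
    or above the threshold; ``interpolate`` is the fractional variant that
    sums the similarities themselves.
    """
    profile = profile or RunProfile("adhoc/DET", "exact", "DET")
    total = np.zeros(len(vectors))
    for f in fields:
        s = vectors[f].to_numpy(float)
        if profile.string_mode == "inexact" and f != "gender":
            if profile.inexact_conversion == THRESHOLD_BINARY:
                total += np.nan_to_num(
                    (s >= profile.similarity_threshold).astype(float), nan=0.0
                )
            else:
                total += np.nan_to_num(s, nan=0.0)
        else:
            total += np.nan_to_num((s == 1.0).astype(float), nan=0.0)
    return total


# ---------------------------------------------------------------------------
# the 17-run matrix


def default_run_matrix() -> list[RunProfile]:
    """The 17 named algorithm/dialect combinations of the benchmark.

    Names follow the package-style convention <family>/<EX|INEX>/<method>:
    R-style runs score missing values as disagreements (8 distinct exact
    weights), MTB/CUPLE/LP-style runs give missing fields zero contribution
    (a 9th distinct weight when a missing pattern occurs), EpiLink appears
    only with exact matching, and the LP-style inexact pair only reports
    positive weights.
    """
    em = dict(method="EM")
    return [
        # --- 9 exact runs
        RunProfile("R/EX/FS", "exact", "FS", AS_DISAGREEMENT),
        RunProfile("R/EX/EM", "exact", "EM", AS_DISAGREEMENT),
        RunProfile("R/EX/EPI", "exact", "EPI", ZERO_CONTRIBUTION),
        RunProfile("MTB/EX/FS", "exact", "FS", ZERO_CONTRIBUTION),
        RunProfile("MTB/EX/EM", "exact", "EM", ZERO_CONTRIBUTION),
        RunProfile("MTB/EX/D", "exact", "DET", ZERO_CONTRIBUTION),
        RunProfile("CU/EX/FS", "exact", "FS", ZERO_CONTRIBUTION),
        RunProfile("LP/EX/FS", "exact", "FS", ZERO_CONTRIBUTION),
        RunProfile("LP/EX/EM", "exact", "EM", ZERO_CONTRIBUTION),
        # --- 8 inexact runs
        RunProfile("R/INEX/FS", "inexact", "FS", AS_DISAGREEMENT, THRESHOLD_BINARY),
        RunProfile("R/INEX/EM", "inexact", "EM", AS_DISAGREEMENT, INTERPOLATE),
        RunProfile("MTB/INEX/FS", "inexact", "FS", ZERO_CONTRIBUTION, INTERPOLATE),
        RunProfile("MTB/INEX/EM", "inexact", "EM", ZERO_CONTRIBUTION, INTERPOLATE),
        RunProfile("MTB/INEX/D", "inexact", "DET", ZERO_CONTRIBUTION, INTERPOLATE),
        RunProfile("CU/INEX/FS", "inexact", "FS", ZERO_CONTRIBUTION, INTERPOLATE),
        RunProfile(
            "LP/INEX/FS", "inexact", "FS", ZERO_CONTRIBUTION, INTERPOLATE,
            positive_only_output=True,
        ),
        RunProfile(
            "LP/INEX/EM", "inexact", "EM", ZERO_CONTRIBUTION, INTERPOLATE,
            positive_only_output=True,
        ),
    ]


def compute_run_weights(
    profile: RunProfile,
    vectors: pd.DataFrame,
    params: MatchParams,
    epi_params: EpiLinkParams | None = None,
    em_init: MatchParams | None = None,
    fields=MATCH_FIELDS,
) -> np.ndarray:
    """Dispatch one profile to its weighting engine.

    ``vectors`` must already be in the profile's string mode.  EM profiles
    estimate their own parameters from the binarized vectors before weighting;
    FS/EpiLink use the supplied defaults.  ``positive_only_output`` truncates
    non-positive weights to NaN (they are unrecoverable downstream).
    """
    if profile.method == "FS":
        w = fs_weight(vectors, params, profile)
    elif profile.method == "EM":
        init = em_init or MatchParams(
            m={f: 0.9 for f in fields}, u=dict(params.u), p=0.01
        )
        binary = binarize_vectors(vectors, profile, fields)
        result = em_estimate(binary, init)
        w = fs_weight(vectors, result.params, profile)
    elif profile.method == "EPI":
        epi = epi_params or EpiLinkParams.from_match_params(params)
        w = epilink_weight(vectors, epi)
    else:
        w = deterministic_weight(vectors, profile, fields)
    if profile.positive_only_output:
        n_drop = int((w <= 0).sum())
        if n_drop:
            log.info("%s: %d non-positive weights truncated", profile.name, n_drop)
        w = np.where(w <= 0, np.nan, w)
    return w
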
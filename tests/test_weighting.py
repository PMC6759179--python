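"""Weighting engines: FS closed forms, EM behaviour, EpiLink, the run matrix."""

import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from linkbench.weighting import (
    AS_DISAGREEMENT,
    INTERPOLATE,
    THRESHOLD_BINARY,
    ZERO_CONTRIBUTION,
    EpiLinkParams,
    MatchParams,
    RunProfile,
    default_match_params,
    default_run_matrix,
    deterministic_weight,
    em_estimate,
    em_posterior,
    epilink_weight,
    fs_weight,
)

FIELDS = ["first_name", "last_name", "gender"]

#: generic informative parameters used throughout (distinct u per field)
PARAMS = MatchParams(
    m={f: 0.95 for f in FIELDS},
    u={"first_name": 0.0001, "last_name": 0.00005, "gender": 0.5},
)


def vectors_from_patterns(patterns):
    """DataFrame of outcome codes from ('agree'|'disagree'|'missing') triples."""
    code = {"agree": 1.0, "disagree": 0.0, "missing": np.nan}
    return pd.DataFrame(
        [[code[o] for o in pat] for pat in patterns], columns=FIELDS
    )


ALL_COMPLETE = list(itertools.product(["agree", "disagree"], repeat=3))
ALL_TRICHOTOMOUS = list(itertools.product(["agree", "disagree", "missing"], repeat=3))


class TestDefaultMatchParams:
    def test_u_is_reciprocal_of_distinct_count_and_m_default(self):
        df = pd.DataFrame(
            {
                "first_name": [f"N{i}" for i in range(1000)],
                "last_name": [f"S{i}" for i in range(1000)],
                "gender": ["F", "M"] * 500,
            }
        )
        params = default_match_params(df, FIELDS)
        assert params.u["gender"] == 0.5
        assert params.u["first_name"] == pytest.approx(0.001)
        assert all(m == 0.95 for m in params.m.values())

    def test_single_valued_field_rejected_with_guidance(self):
        df = pd.DataFrame({"gender": ["F"] * 5})
        with pytest.raises(ValueError, match="uninformative"):
            default_match_params(df, ["gender"])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            default_match_params(pd.DataFrame(columns=FIELDS), FIELDS)

    def test_invalid_probability_ordering_rejected(self):
        with pytest.raises(ValueError, match="0 < u < m < 1"):
            MatchParams(m={"x": 0.4}, u={"x": 0.5})


class TestFellegiSunter:
    def test_gender_agreement_closed_form(self):
        params = MatchParams(m={"gender": 0.95}, u={"gender": 0.5})
        v = pd.DataFrame({"gender": [1.0, 0.0]})
        w = fs_weight(v, params)
        assert w[0] == pytest.approx(np.log2(0.95 / 0.5), abs=1e-12)  # ~0.926
        assert w[1] == pytest.approx(np.log2(0.05 / 0.5), abs=1e-12)  # ~-3.322

    def test_missing_gender_ranks_above_full_disagreement_under_zero_contribution(self):
        v = vectors_from_patterns(
            [("disagree", "disagree", "missing"), ("disagree", "disagree", "disagree")]
        )
        profile = RunProfile("t", "exact", "FS", ZERO_CONTRIBUTION)
        w = fs_weight(v, PARAMS, profile)
        assert w[0] > w[1]

    def test_missing_scored_as_disagreement_collapses_the_two_patterns(self):
        v = vectors_from_patterns(
            [("disagree", "disagree", "missing"), ("disagree", "disagree", "disagree")]
        )
        profile = RunProfile("t", "exact", "FS", AS_DISAGREEMENT)
        w = fs_weight(v, PARAMS, profile)
        assert w[0] == pytest.approx(w[1], abs=1e-12)

    @pytest.mark.parametrize("policy", [ZERO_CONTRIBUTION, AS_DISAGREEMENT])
    def test_matches_brute_force_on_all_27_trichotomous_patterns(self, policy):
        v = vectors_from_patterns(ALL_TRICHOTOMOUS)
        profile = RunProfile("t", "exact", "FS", policy)
        w = fs_weight(v, PARAMS, profile)
        m = [PARAMS.m[f] for f in FIELDS]
        u = [PARAMS.u[f] for f in FIELDS]
        for k, pat in enumerate(ALL_TRICHOTOMOUS):
            assert w[k] == pytest.approx(
                oracles.fs_weight_brute(pat, m, u, policy), abs=1e-12
            )

    def test_flipping_disagree_to_agree_strictly_increases_weight(self):
        for k, pat in enumerate(ALL_COMPLETE):
            for i in range(3):
                if pat[i] == "disagree":
                    flipped = list(pat)
                    flipped[i] = "agree"
                    v = vectors_from_patterns([pat, tuple(flipped)])
                    w = fs_weight(v, PARAMS)
                    assert w[1] > w[0]

    def test_complete_patterns_yield_eight_distinct_weights(self):
        w = fs_weight(vectors_from_patterns(ALL_COMPLETE), PARAMS)
        assert len(np.unique(w)) == 8

    def test_field_priority_order_matches_u_ordering(self):
        """With u_last < u_first < u_gender the agreement-pattern ranking is
        FLG > FL > LG > FG > L > F > G > none."""
        named = {
            "FLG": ("agree", "agree", "agree"),
            "FL": ("agree", "agree", "disagree"),
            "LG": ("disagree", "agree", "agree"),
            "FG": ("agree", "disagree", "agree"),
            "L": ("disagree", "agree", "disagree"),
            "F": ("agree", "disagree", "disagree"),
            "G": ("disagree", "disagree", "agree"),
            "none": ("disagree", "disagree", "disagree"),
        }
        v = vectors_from_patterns(list(named.values()))
        w = fs_weight(v, PARAMS)
        order = [name for name, _ in sorted(zip(named, w), key=lambda t: -t[1])]
        assert order == ["FLG", "FL", "LG", "FG", "L", "F", "G", "none"]

    def test_interpolated_similarity_blends_the_two_weights(self):
        params = MatchParams(m={"last_name": 0.9}, u={"last_name": 0.1})
        profile = RunProfile("t", "inexact", "FS", inexact_conversion=INTERPOLATE)
        s = 0.7
        w = fs_weight(pd.DataFrame({"last_name": [s]}), params, profile)
        aw, dw = np.log2(0.9 / 0.1), np.log2(0.1 / 0.9)
        assert w[0] == pytest.approx(s * aw + (1 - s) * dw, abs=1e-12)

    def test_threshold_binary_snaps_similarities(self):
        params = MatchParams(m={"last_name": 0.9}, u={"last_name": 0.1})
        profile = RunProfile(
            "t", "inexact", "FS", inexact_conversion=THRESHOLD_BINARY,
            similarity_threshold=0.95,
        )
        w = fs_weight(pd.DataFrame({"last_name": [0.96, 0.94]}), params, profile)
        assert w[0] == pytest.approx(np.log2(9.0), abs=1e-12)
        assert w[1] == pytest.approx(np.log2(1 / 9), abs=1e-12)

    def test_similarity_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="similarities"):
            fs_weight(pd.DataFrame({"gender": [1.5]}),
                      MatchParams(m={"gender": 0.95}, u={"gender": 0.5}))


class TestEM:
    def test_posterior_half_when_evidence_balances(self):
        # p*m = 0.1*0.9 = 0.09 equals (1-p)*u = 0.9*0.1
        params = MatchParams(m={"x": 0.9}, u={"x": 0.1}, p=0.1)
        g = em_posterior(pd.DataFrame({"x": [1.0]}), params)
        assert g[0] == pytest.approx(0.5, abs=1e-12)

    def test_log_likelihood_never_decreases(self):
        rng = np.random.default_rng(0)
        z = rng.random(2000) < 0.3
        v = pd.DataFrame(
            {
                f: np.where(z, rng.random(2000) < 0.9, rng.random(2000) < 0.2)
                for f in FIELDS
            },
            dtype=float,
        )
        init = MatchParams(
            m={f: 0.7 for f in FIELDS}, u={f: 0.3 for f in FIELDS}, p=0.5
        )
        result = em_estimate(v, init)
        trace = np.array(result.loglik_trace)
        assert (np.diff(trace) >= -1e-8).all()

    def test_single_pattern_flagged_degenerate(self):
        v = pd.DataFrame({f: [1.0] * 50 for f in FIELDS})
        init = MatchParams(
            m={f: 0.9 for f in FIELDS}, u={f: 0.1 for f in FIELDS}, p=0.1
        )
        result = em_estimate(v, init)
        assert result.degenerate and not result.converged

    def test_recovers_parameters_from_small_simulation(self):
        # three fields: the two-class conditional-independence mixture is not
        # identifiable from fewer binary fields
        rng = np.random.default_rng(1)
        n = 20_000
        p = 0.1
        m = {"a": 0.95, "b": 0.9, "c": 0.85}
        u = {"a": 0.02, "b": 0.1, "c": 0.05}
        z = rng.random(n) < p
        v = pd.DataFrame(
            {
                f: np.where(z, rng.random(n) < m[f], rng.random(n) < u[f])
                for f in m
            },
            dtype=float,
        )
        init = MatchParams(m={f: 0.8 for f in m}, u={f: 0.1 for f in m}, p=0.01)
        result = em_estimate(v, init)
        assert result.converged
        assert abs(result.params.p - p) < 0.02
        for f in m:
            assert abs(result.params.m[f] - m[f]) < 0.02
            assert abs(result.params.u[f] - u[f]) < 0.02


class TestEpiLink:
    def test_full_agreement_scores_one_full_disagreement_zero(self):
        params = EpiLinkParams.from_match_params(PARAMS)
        v = vectors_from_patterns(
            [("agree", "agree", "agree"), ("disagree", "disagree", "disagree")]
        )
        w = epilink_weight(v, params)
        assert w[0] == pytest.approx(1.0, abs=1e-12)
        assert w[1] == pytest.approx(0.0, abs=1e-12)

    def test_weighted_average_arithmetic(self):
        # field weights 2, 4, 1 via f = (1-e)/2^w with e = 0.5
        params = EpiLinkParams(
            e={f: 0.5 for f in FIELDS},
            f={"first_name": 0.125, "last_name": 0.03125, "gender": 0.25},
        )
        assert params.weights == pytest.approx(
            {"first_name": 2.0, "last_name": 4.0, "gender": 1.0}
        )
        v = vectors_from_patterns([("agree", "disagree", "agree")])
        assert epilink_weight(v, params)[0] == pytest.approx(3 / 7, abs=1e-12)

    def test_missing_fields_drop_from_both_sums(self):
        params = EpiLinkParams(
            e={f: 0.5 for f in FIELDS},
            f={"first_name": 0.125, "last_name": 0.03125, "gender": 0.25},
        )
        v = vectors_from_patterns([("agree", "missing", "disagree")])
        assert epilink_weight(v, params)[0] == pytest.approx(2 / 3, abs=1e-12)

    def test_all_fields_missing_flagged_nan(self):
        params = EpiLinkParams.from_match_params(PARAMS)
        v = vectors_from_patterns([("missing", "missing", "missing")])
        assert np.isnan(epilink_weight(v, params)[0])

    def test_bounds_on_all_trichotomous_patterns(self):
        params = EpiLinkParams.from_match_params(PARAMS)
        v = vectors_from_patterns(ALL_TRICHOTOMOUS[:-1])  # exclude all-missing
        w = epilink_weight(v, params)
        assert np.nanmin(w) >= 0.0 and np.nanmax(w) <= 1.0

    def test_uninformative_parameters_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            EpiLinkParams(e={"x": 0.5}, f={"x": 0.9})


class TestDeterministic:
    @pytest.mark.parametrize(
        "pattern, expected",
        [
            (("agree", "agree", "agree"), 3),
            (("disagree", "disagree", "disagree"), 0),
            (("agree", "disagree", "missing"), 1),
            (("missing", "missing", "missing"), 0),
        ],
    )
    def test_counts_agreements_missing_never_counts(self, pattern, expected):
        w = deterministic_weight(vectors_from_patterns([pattern]))
        assert w[0] == expected

    def test_fractional_variant_sums_similarities(self):
        profile = RunProfile("t", "inexact", "DET", inexact_conversion=INTERPOLATE)
        v = pd.DataFrame(
            {"first_name": [0.8], "last_name": [0.5], "gender": [1.0]}
        )
        assert deterministic_weight(v, profile)[0] == pytest.approx(2.3)

    def test_threshold_variant_counts_high_similarities(self):
        profile = RunProfile(
            "t", "inexact", "DET", inexact_conversion=THRESHOLD_BINARY,
            similarity_threshold=0.9,
        )
        v = pd.DataFrame(
            {"first_name": [0.95], "last_name": [0.5], "gender": [1.0]}
        )
        assert deterministic_weight(v, profile)[0] == 2


class TestRunMatrix:
    def test_seventeen_uniquely_named_profiles(self):
        matrix = default_run_matrix()
        assert len(matrix) == 17
        names = [p.name for p in matrix]
        assert len(set(names)) == 17

    def test_epilink_appears_only_with_exact_matching(self):
        for p in default_run_matrix():
            if p.method == "EPI":
                assert p.string_mode == "exact"
                assert p.missing_policy == ZERO_CONTRIBUTION

    def test_nine_exact_and_eight_inexact_runs(self):
        modes = [p.string_mode for p in default_run_matrix()]
        assert modes.count("exact") == 9
        assert modes.count("inexact") == 8

    def test_positive_only_truncation_restricted_to_lp_inexact(self):
        for p in default_run_matrix():
            assert p.positive_only_output == (
                p.name in ("LP/INEX/FS", "LP/INEX/EM")
            )

    def test_epilink_with_missing_as_disagreement_rejected(self):
        with pytest.raises(ValueError, match="EpiLink"):
            RunProfile("bad", "exact", "EPI", AS_DISAGREEMENT)
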
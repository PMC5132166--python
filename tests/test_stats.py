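import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from whistledialog.core import Channel
from whistledialog.stats import (
    binomial_z_test,
    fit_logistic_mixed,
    listener_concordance,
    paired_signed_rank,
    round_records,
    agreement_model,
    winner_model,
    within_subject_change,
)
from whistledialog.synthetic import ListenerModel, simulate_listeners


def brute_force_signed_rank_p(diffs, side="two_sided"):
    """Exhaustive sign-flip null: every 2^m assignment of signs to |d|."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    m = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = m * (m + 1) / 4.0
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=m):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if side == "two_sided":
            hit = abs(w - mu) >= abs(w_obs - mu) - 1e-9
        elif side == "greater":
            hit = w >= w_obs - 1e-9
        else:
            hit = w <= w_obs + 1e-9
        count += hit
        total += 1
    return count / total


class TestPairedSignedRank:
    def test_equal_vectors(self):
        res = paired_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_all_positive_five_pairs(self):
        # positive-rank sum 15, centered S = 15 - 7.5 = 7.5
        res = paired_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.statistic == pytest.approx(7.5)
        assert res.notes["w_plus"] == pytest.approx(15.0)
        assert res.p_value == pytest.approx(0.0625)  # 2/32

    def test_exact_matches_enumeration_random(self, rng):
        for _ in range(20):
            m = int(rng.integers(3, 9))
            x = rng.normal(0, 1, m)
            y = rng.normal(0, 1, m)
            res = paired_signed_rank(x, y)
            expected = brute_force_signed_rank_p(x - y)
            assert res.p_value == pytest.approx(expected)

    def test_exact_with_ties_matches_enumeration(self):
        x = np.array([1.0, 1.0, 2.0, -2.0, 3.0, 0.5])
        y = np.zeros(6)
        res = paired_signed_rank(x, y)
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(x - y))

    def test_one_sided(self, rng):
        x = rng.normal(1, 1, 7)
        y = rng.normal(0, 1, 7)
        res = paired_signed_rank(x, y, side="greater")
        assert res.p_value == pytest.approx(
            brute_force_signed_rank_p(x - y, "greater")
        )

    def test_normal_approx_close_to_exact(self, rng):
        x = rng.normal(0.3, 1, 24)
        y = rng.normal(0.0, 1, 24)
        exact = paired_signed_rank(x, y)
        approx = paired_signed_rank(x, y, exact_max_n=5)
        assert approx.notes["mode"] == "normal_approx"
        assert abs(exact.p_value - approx.p_value) < 0.02

    def test_zero_differences_dropped(self):
        res = paired_signed_rank([1.0, 2.0, 5.0], [1.0, 2.0, 1.0])
        assert res.notes["m_nonzero"] == 1

    def test_sign_convention(self):
        # x < y everywhere -> W+ = 0, S = -m(m+1)/4 = -3
        res = paired_signed_rank([0, 0, 0], [1, 2, 3])
        assert res.statistic == pytest.approx(-3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            paired_signed_rank([], [])


class TestBinomialZ:
    def test_twentyone_of_thirty(self):
        res = binomial_z_test(21, 30, 0.5, side="one_sided")
        assert round(res.statistic, 2) == 2.19
        assert res.p_value == pytest.approx(0.014, abs=0.001)
        assert res.notes["exact_p"] == pytest.approx(0.021, abs=0.002)

    def test_null_center(self):
        res = binomial_z_test(15, 30, 0.5)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_all_successes(self):
        res = binomial_z_test(30, 30, 0.5)
        assert res.statistic == pytest.approx(0.5 / math.sqrt(0.25 / 30))
        assert res.statistic == pytest.approx(5.477, abs=0.001)

    def test_antisymmetry_in_k(self):
        for k in range(0, 31):
            z1 = binomial_z_test(k, 30, 0.5).statistic
            z2 = binomial_z_test(30 - k, 30, 0.5).statistic
            assert z1 == pytest.approx(-z2)

    def test_exact_close_to_continuity_corrected_normal(self):
        # the uncorrected z is the headline statistic; its continuity-
        # corrected tail tracks the exact binomial tail closely
        for n in (30, 50, 100):
            for k in range(n // 2, n):
                res = binomial_z_test(k, n, 0.5, side="one_sided")
                if abs(res.statistic) > 2.5:
                    break
                sigma = math.sqrt(0.25 * n)
                corrected = sps.norm.sf((k - 0.5 - 0.5 * n) / sigma)
                assert abs(corrected - res.notes["exact_p"]) < 0.02

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            binomial_z_test(1, 0, 0.5)
        with pytest.raises(ValueError):
            binomial_z_test(5, 3, 0.5)
        with pytest.raises(ValueError):
            binomial_z_test(1, 3, 1.0)


def simulate_mixed(rng, n_groups=45, n_per=3, beta=(0.0, 2.0), sigma=1.0):
    groups = np.repeat(np.arange(n_groups), n_per)
    x = rng.normal(0, 1, groups.size)
    b = rng.normal(0, sigma, n_groups)[groups]
    eta = beta[0] + beta[1] * x + b
    y = (rng.random(groups.size) < 1 / (1 + np.exp(-eta))).astype(float)
    X = np.column_stack([np.ones(groups.size), x])
    return X, y, groups, x


class TestLogisticMixed:
    def test_recovers_slope(self, rng):
        X, y, groups, _ = simulate_mixed(rng, n_groups=120, n_per=4)
        fit = fit_logistic_mixed(X, y, groups)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(2.0, abs=3 * fit.beta_se[1])

    def test_null_slope_near_zero(self, rng):
        X, y, groups, _ = simulate_mixed(rng, beta=(0.0, 0.0))
        fit = fit_logistic_mixed(X, y, groups)
        assert abs(fit.beta[1]) < 3 * fit.beta_se[1]

    def test_separation_flagged_and_penalized(self):
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(20), 3)
        x = rng.normal(0, 1, 60)
        y = (x > 0).astype(float)  # perfectly separable
        fit = fit_logistic_mixed(np.column_stack([np.ones(60), x]), y, groups)
        assert fit.separation or fit.penalized

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            fit_logistic_mixed(np.ones((5, 1)), np.ones(4), np.arange(4))


def make_records(rng, n_pairs=45, n_rounds=3, accent_effect=2.0, noise=1.0):
    """Synthetic per-round records: winner channel driven by the accent
    difference via a logistic model with pair random effects."""
    rows = []
    for p in range(n_pairs):
        b = rng.normal(0, 0.5)
        for r in range(n_rounds):
            d_accent = rng.normal(0, noise)
            eta = accent_effect * d_accent + b
            winner_is_a = rng.random() < 1 / (1 + np.exp(-eta))
            rows.append(
                {
                    "pair_id": f"p{p}",
                    "round_index": r,
                    "resolved": True,
                    "winner": "A" if winner_is_a else "B",
                    "agreement": bool(rng.random() < 0.7),
                    "agreement_known": True,
                    "d_dur_accent": d_accent,
                    "abs_d_dur_accent": abs(d_accent),
                }
            )
    return pd.DataFrame(rows)


class TestWinnerModel:
    def test_recovers_effect_direction(self, rng):
        records = make_records(rng, n_pairs=60)
        fit = winner_model(records, predictors=["d_dur_accent"], seed=5)
        est, se = fit.coefficients["d_dur_accent"]
        assert est > 0
        assert est == pytest.approx(2.0, abs=3 * se)

    def test_focal_choice_flips_sign_only(self, rng):
        records = make_records(rng, n_pairs=40)
        fit1 = winner_model(records, predictors=["d_dur_accent"], seed=1,
                            test_interactions=False)
        # relabel channels: flips winner and difference signs
        flipped = records.copy()
        flipped["winner"] = flipped["winner"].map({"A": "B", "B": "A"})
        flipped["d_dur_accent"] = -flipped["d_dur_accent"]
        fit2 = winner_model(flipped, predictors=["d_dur_accent"], seed=1,
                            test_interactions=False)
        est1 = fit1.coefficients["d_dur_accent"][0]
        est2 = fit2.coefficients["d_dur_accent"][0]
        assert abs(est1) == pytest.approx(abs(est2), rel=1e-3)

    def test_all_zero_differences_intercept_only(self, rng):
        records = make_records(rng, n_pairs=20)
        records["d_dur_accent"] = 0.0
        fit = winner_model(records, predictors=["d_dur_accent"], seed=0)
        assert "d_dur_accent" not in fit.coefficients
        assert fit.notes.get("constant_predictors_excluded") == ["d_dur_accent"]

    def test_unresolved_rounds_excluded(self, rng):
        records = make_records(rng, n_pairs=30)
        records.loc[records.index[:10], "resolved"] = False
        fit = winner_model(records, predictors=["d_dur_accent"], seed=0,
                           test_interactions=False)
        assert fit.n_obs == len(records) - 10

    def test_no_resolved_rounds_rejected(self, rng):
        records = make_records(rng, n_pairs=5)
        records["resolved"] = False
        with pytest.raises(ValueError):
            winner_model(records, predictors=["d_dur_accent"], seed=0)


class TestAgreementModel:
    def test_recovers_positive_effect(self, rng):
        rows = []
        for p in range(60):
            b = rng.normal(0, 0.5)
            for r in range(3):
                abs_diff = abs(rng.normal(0, 1.0))
                eta = -1.0 + 2.0 * abs_diff + b
                rows.append(
                    {
                        "pair_id": f"p{p}",
                        "round_index": r,
                        "resolved": True,
                        "winner": "A",
                        "agreement": bool(
                            rng.random() < 1 / (1 + np.exp(-eta))
                        ),
                        "agreement_known": True,
                        "abs_d_dur_accent": abs_diff,
                    }
                )
        fit = agreement_model(
            pd.DataFrame(rows), predictors=["abs_d_dur_accent"]
        )
        est, se = fit.coefficients["abs_d_dur_accent"]
        assert est > 0
        test = [t for t in fit.term_tests if "abs_d_dur_accent" in t.method][0]
        assert test.p_value < 0.05

    def test_constant_predictor_flagged(self, rng):
        records = make_records(rng, n_pairs=20)
        records["abs_d_dur_accent"] = 1.0
        fit = agreement_model(records, predictors=["abs_d_dur_accent"])
        assert fit.notes.get("constant_predictors_excluded") == [
            "abs_d_dur_accent"
        ]


class TestWithinSubjectChange:
    def test_identical_means(self):
        res = within_subject_change([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_missing_units_dropped(self):
        res = within_subject_change(
            [1.0, 2.0, math.nan, 4.0], [0.5, 2.5, 3.0, math.nan]
        )
        assert res.notes["n_excluded"] == 2
        assert res.n == 2

    def test_single_unit(self):
        res = within_subject_change([1.0], [0.0])
        assert res.p_value == pytest.approx(1.0)  # m=1, two-sided exact

    def test_detects_shift_at_28_pairs(self, rng):
        x = rng.normal(0.27, 0.05, 28)
        y = rng.normal(0.17, 0.05, 28)
        res = within_subject_change(x, y)
        assert res.p_value < 0.01 and res.statistic > 0


class TestListenerConcordance:
    def test_seventy_percent_regime(self):
        model = ListenerModel(p_choose_accentuated=0.7)
        responses = simulate_listeners(model, n_listeners=30, n_dialogs=3, seed=11)
        res, per_dialog = listener_concordance(responses)
        assert res.notes["pooled_proportion"] == pytest.approx(0.7, abs=0.12)
        assert res.statistic > 0
        assert res.p_value < 0.05
        assert len(per_dialog) == 3

    def test_null_usually_nonsignificant(self):
        model = ListenerModel(p_choose_accentuated=0.5)
        hits = 0
        for seed in range(20):
            responses = simulate_listeners(model, 30, 3, seed=seed)
            res, _ = listener_concordance(responses)
            hits += res.p_value < 0.05
        assert hits <= 4

    def test_all_correct_separation_flagged(self):
        model = ListenerModel(p_choose_accentuated=1.0)
        responses = simulate_listeners(model, 10, 2, seed=0)
        res, _ = listener_concordance(responses)
        assert res.notes["pooled_proportion"] == 1.0
        assert res.notes.get("separation")

    def test_single_dialog_reduced_model(self):
        model = ListenerModel(p_choose_accentuated=0.7)
        responses = simulate_listeners(model, 30, 1, seed=3)
        res, _ = listener_concordance(responses)
        assert res.notes.get("dialog_variance_dropped")

    def test_single_listener_rejected(self):
        model = ListenerModel()
        responses = simulate_listeners(model, 1, 3, seed=0)
        with pytest.raises(ValueError):
            listener_concordance(responses)


class TestRoundRecords:
    def test_differences_and_outcome(self, hand_dialog):
        import dataclasses

        d = dataclasses.replace(
            hand_dialog, claim_A=True, claim_B=False, fair_B=True
        )
        records = round_records([d])
        assert len(records) == 1
        row = records.iloc[0]
        assert row["winner"] == "A" and row["agreement"]
        assert row["d_n_whistles"] == 1  # 4 vs 3
        assert row["abs_d_mean_duration"] == pytest.approx(0.075)
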
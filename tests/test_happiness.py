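"""Decayed-history arithmetic, model predictions and happiness fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from banditmood.choice import ChoiceParams, simulate_agent
from banditmood.happiness import (HAPPINESS_MODELS, build_term_history,
                                  decayed_series, decayed_sum,
                                  fit_happiness_model,
                                  fit_happiness_two_stage, predict_happiness,
                                  swap_learning_rate_refit)
from banditmood.task import generate_schedule, stable_config, volatile_config

from conftest import make_session


class TestDecayedSums:
    def test_memoryless_limit(self):
        assert decayed_sum([3.0, -1.0, 2.0], gamma=0.0, t=3) == 2.0

    def test_unweighted_sum_at_gamma_one(self):
        assert decayed_sum(np.ones(5), gamma=1.0, t=5) == 5.0

    def test_direct_evaluation(self):
        assert decayed_sum([1.0, 0.0, 1.0], gamma=0.5, t=3) == 1.25

    @given(gamma=st.floats(0, 1),
           values=st.lists(st.floats(-1, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_recursive_matches_brute_force(self, gamma, values):
        """S_t = sum_j gamma^(t-j) x_j, computed two independent ways."""
        series = decayed_series(values, gamma)
        t = len(values)
        brute = sum(gamma ** (t - j) * x for j, x in enumerate(values, 1))
        assert np.isclose(series[-1], brute, atol=1e-9)


class TestTermHistory:
    def test_subjective_ppe_signs(self):
        session = make_session(winners="AB", choices="AA",
                               reward_A=[40, 40], reward_B=[10, 10])
        # alpha=0.5: p_A = 0.5 then 0.75
        terms = build_term_history(session, 0.5)
        assert np.allclose(terms["ppe_hat"], [1 - 0.5, 0 - 0.75])

    def test_objective_ppe_uses_block_contingency(self):
        session = make_session(winners="AA", choices="AB",
                               reward_A=[40, 40], reward_B=[10, 10],
                               best_car="AA")
        terms = build_term_history(session, 0.3)
        # trial 1: chose best car and won -> 1 - 0.8; trial 2: chose the
        # 20% car and lost -> 0 - 0.2
        assert np.allclose(terms["ppe_obj"], [0.2, -0.2])

    def test_subjective_rpe_hand_value(self):
        """Win of 40 points (0.5 rescaled) at belief 0.6: RPE = 0.5 - 0.3."""
        session = make_session(winners="AA", choices="AA",
                               reward_A=[40, 40], reward_B=[10, 10])
        terms = build_term_history(session, 0.2)
        # trial 2 belief: 0.5 + 0.2*0.5 = 0.6
        assert np.isclose(terms["rpe_hat"].iloc[1], 0.5 - 0.6 * 0.5)

    def test_win_and_loss_flags_are_complementary(self, simulated_session):
        terms = build_term_history(simulated_session, 0.4)
        assert np.allclose(terms["win"] + terms["loss"], 1.0)


def test_equal_weight_model_reduces_to_decayed_win_average(simulated_session):
    """With w_P = w_PPE = w the probability + PPE model collapses to
    w0 + w * decayed sum of (win - 0.5): the probability terms cancel
    against the expectation inside the prediction error."""
    terms = build_term_history(simulated_session, 0.47)
    rating_trials = simulated_session.schedule.rating_trials
    w0, w, gamma = 0.3, 1.1, 0.6
    pred = predict_happiness("p_hat_ppe_hat", w0,
                             {"w_p_hat_c": w, "w_ppe_hat": w}, gamma, terms,
                             rating_trials)
    wins_centred = terms["win"].to_numpy() - 0.5
    closed_form = w0 + w * decayed_series(wins_centred, gamma)[rating_trials - 1]
    assert np.allclose(pred, closed_form, atol=1e-12)


def test_zero_weights_predict_constant_baseline(simulated_session):
    terms = build_term_history(simulated_session, 0.47)
    pred = predict_happiness("p_hat_ppe_hat", 42.0,
                             {"w_p_hat_c": 0.0, "w_ppe_hat": 0.0}, 0.5,
                             terms, simulated_session.schedule.rating_trials)
    assert np.allclose(pred, 42.0)


def _session_with_model_ratings(model_id, w0, weights, gamma, rp=None,
                                seed=55, noise_sd=0.0, env="stable"):
    config = (stable_config if env == "stable" else volatile_config)(seed=seed)
    schedule = generate_schedule(config)
    params = ChoiceParams(model_id="additive", alpha=0.25, beta=10.0, phi=0.5)
    session = simulate_agent(schedule, params, seed=seed + 1)
    terms = build_term_history(session, params.alpha)
    trials = schedule.rating_trials
    pred = predict_happiness(model_id, w0, weights, gamma, terms, trials,
                             rp=rp)
    rng = np.random.default_rng(seed + 2)
    session.ratings = {int(t): float(r) for t, r in
                       zip(trials, pred + rng.normal(0, noise_sd, len(trials)))}
    return session, terms


class TestFitting:
    def test_noise_free_ratings_recovered_exactly(self):
        truth = {"w_p_hat_c": 0.8, "w_ppe_hat": 1.3}
        session, terms = _session_with_model_ratings(
            "p_hat_ppe_hat", 0.25, truth, gamma=0.6)
        fit = fit_happiness_model(session, terms, "p_hat_ppe_hat",
                                  zscore=False)
        assert abs(fit.gamma - 0.6) < 1e-4
        assert np.isclose(fit.w0, 0.25, atol=1e-4)
        for k, v in truth.items():
            assert np.isclose(fit.weights[k], v, atol=1e-4)
        assert fit.var_explained > 1 - 1e-9
        assert fit.r2 > 1 - 1e-9

    def test_pure_noise_explains_little_variance(self):
        session, terms = _session_with_model_ratings(
            "ppe_hat", 0.0, {"w_ppe_hat": 0.0}, gamma=0.5, noise_sd=1.0)
        fit = fit_happiness_model(session, terms, "ppe_hat")
        assert fit.r2 < 0.35

    def test_constant_ratings_flagged_degenerate(self, simulated_session):
        session = simulated_session
        session = make_session(
            winners=session.schedule.winner, choices=session.choices,
            reward_A=session.schedule.reward_A,
            reward_B=session.schedule.reward_B,
            ratings={t: 50.0 for t in range(5, 60, 5)})
        terms = build_term_history(session, 0.4)
        fit = fit_happiness_model(session, terms, "ppe_hat", zscore=True)
        assert fit.flagged and "degenerate" in fit.flag_reason

    def test_zscored_fit_centres_baseline_near_zero(self):
        session, terms = _session_with_model_ratings(
            "p_hat_ppe_hat", 5.0, {"w_p_hat_c": 0.7, "w_ppe_hat": 1.2},
            gamma=0.6, noise_sd=0.3)
        fit = fit_happiness_model(session, terms, "p_hat_ppe_hat",
                                  zscore=True)
        assert abs(fit.w0) < 0.5

    def test_raw_fit_keeps_baseline_on_rating_scale(self):
        session, terms = _session_with_model_ratings(
            "reward_mean", 60.0, {"w_r_c": 0.4}, gamma=0.4, noise_sd=2.0)
        fit = fit_happiness_model(session, terms, "reward_mean", zscore=False)
        assert 0.0 <= fit.w0 <= 100.0

    def test_reference_point_recovered_from_noise_free_ratings(self):
        session, terms = _session_with_model_ratings(
            "reward_refpoint", 50.0, {"w_r": 0.5}, gamma=0.5, rp=14.0)
        fit = fit_happiness_model(session, terms, "reward_refpoint",
                                  zscore=False)
        assert np.isclose(fit.rp, 14.0, atol=0.2)
        assert np.isclose(fit.weights["w_r"], 0.5, atol=0.01)

    def test_win_loss_weights_follow_sign_convention(self):
        session, terms = _session_with_model_ratings(
            "win_loss", 0.0, {"w_win": 0.9, "w_loss": 1.4}, gamma=0.55)
        fit = fit_happiness_model(session, terms, "win_loss", zscore=False)
        assert np.isclose(fit.weights["w_win"], 0.9, atol=1e-3)
        assert np.isclose(fit.weights["w_loss"], 1.4, atol=1e-3)

    def test_too_few_ratings_rejected(self):
        session = make_session(winners="AABAB" * 4, choices="ABABA" * 4,
                               reward_A=[40] * 20, reward_B=[10] * 20,
                               ratings={4: 60.0, 8: 55.0})
        terms = build_term_history(session, 0.3)
        with pytest.raises(ValueError, match="at least 5"):
            fit_happiness_model(session, terms, "ppe_hat")

    def test_unknown_model_rejected(self, simulated_session):
        terms = build_term_history(simulated_session, 0.4)
        with pytest.raises(ValueError, match="unknown"):
            fit_happiness_model(simulated_session, terms, "nonesuch")

    def test_parameter_counts_match_model_table(self):
        expected = {"ppe_hat": 3, "rpe_hat": 3, "ppe_obj": 3, "rpe_obj": 3,
                    "p_hat_ppe_hat": 4, "ev_hat_ppe_hat": 4,
                    "ev_hat_rpe_hat": 4, "p_hat_rpe_hat": 4,
                    "reward_mean": 3, "reward_refpoint": 4, "win_loss": 4}
        assert {m: k for m, (_, k) in HAPPINESS_MODELS.items()} == expected


class TestTwoStageAndSwap:
    def test_swap_with_identical_alpha_is_noop(self):
        session, terms = _session_with_model_ratings(
            "p_hat_ppe_hat", 0.0, {"w_p_hat_c": 0.7, "w_ppe_hat": 1.2},
            gamma=0.6, noise_sd=0.4)
        base = fit_happiness_model(session, terms, "p_hat_ppe_hat")
        swapped = swap_learning_rate_refit(session, 0.25)
        assert np.isclose(base.gamma, swapped.gamma, atol=1e-9)
        assert np.isclose(base.weights["w_ppe_hat"],
                          swapped.weights["w_ppe_hat"], atol=1e-9)

    def test_swap_perturbs_fit_but_not_gamma_much(self):
        session, _ = _session_with_model_ratings(
            "p_hat_ppe_hat", 0.0, {"w_p_hat_c": 0.7, "w_ppe_hat": 1.2},
            gamma=0.6, noise_sd=0.4)
        own = swap_learning_rate_refit(session, 0.25)
        other = swap_learning_rate_refit(session, 0.47)
        assert abs(own.gamma - other.gamma) < 0.15

    def test_two_stage_protocol_fits_both_environments(self):
        sessions, terms = {}, {}
        for env in ("stable", "volatile"):
            sessions[env], terms[env] = _session_with_model_ratings(
                "p_hat_ppe_hat", 0.0, {"w_p_hat_c": 0.7, "w_ppe_hat": 1.2},
                gamma=0.6, noise_sd=0.4, env=env,
                seed=60 if env == "stable" else 70)
        joint_gamma, fits = fit_happiness_two_stage(sessions, terms,
                                                    "p_hat_ppe_hat")
        assert 0.0 <= joint_gamma <= 1.0
        for env, fit in fits.items():
            assert abs(fit.gamma - 0.6) < 0.2
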
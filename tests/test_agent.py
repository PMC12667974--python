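import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm, ttest_ind

from pavbias.agent import (
    LatentState,
    SessionParameters,
    SubjectParameters,
    action_weights,
    choice_probability,
    inverse_transform,
    session2_parameters,
    session_loglik,
    simulate_session,
    transform,
    update_values,
)
from pavbias.task import Action, TaskDesign, condition_from_token, correct_action

finite_eta = st.lists(st.floats(-3, 3), min_size=7, max_size=7).map(np.array)


class TestTransform:
    def test_zero_vector_maps_to_neutral_parameters(self):
        p = transform(np.zeros(7))
        assert p.eps == 0.5 and p.xi == 0.5
        assert p.rho_rew == 1.0 and p.rho_pun == 1.0
        assert p.go_bias == p.pi_rew == p.pi_pun == 0.0

    def test_probit_matches_normal_cdf_oracle(self):
        # independent normal-CDF evaluation pins the probit convention
        eta = np.zeros(7)
        eta[0] = 1.6449
        assert transform(eta).eps == pytest.approx(norm.cdf(1.6449), abs=1e-12)
        assert transform(eta).eps == pytest.approx(0.95, abs=1e-4)

    @given(finite_eta)
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, eta):
        assert np.allclose(inverse_transform(transform(eta)), eta, atol=1e-10)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            transform(np.array([np.nan, 0, 0, 0, 0, 0, 0]))


class TestSessionTwoParameters:
    def test_zero_delta_reproduces_session1(self):
        eta = np.array([-0.3, 0.8, 0.5, 0.1, 0.7, 0.2, -1.0])
        sp = SubjectParameters(eta1=eta, delta=np.zeros(7))
        assert sp.session2() == sp.session1()

    def test_identity_transform_on_pi(self):
        sp = SubjectParameters(eta1=np.zeros(7), delta=np.array([0, 0, 0, 0, 0.5, 0, 0]))
        assert session2_parameters(sp).pi_rew == pytest.approx(0.5)

    def test_bounded_parameters_never_leave_bounds(self):
        sp = SubjectParameters(eta1=np.zeros(7), delta=np.array([0, 0, 0, 0, 0, 0, 3.0]))
        assert session2_parameters(sp).xi < 1.0
        # even an extreme shift saturates at the bound instead of escaping it
        sp = SubjectParameters(eta1=np.zeros(7), delta=np.array([0, 0, 0, 0, 0, 0, 30.0]))
        assert session2_parameters(sp).xi <= 1.0


class TestValueUpdates:
    def setup_method(self):
        self.gw = condition_from_token("gw")
        self.ngal = condition_from_token("ngal")

    def test_update_moves_toward_scaled_outcome(self):
        p = SessionParameters(0.5, 2.0, 2.0, 0.0, 0.0, 0.0, 0.1)
        state = update_values(LatentState.zeros(), self.gw, Action.GO, 1, p)
        assert state.Q[0, 1] == pytest.approx(1.0)
        assert state.V[0] == pytest.approx(1.0)

    def test_zero_outcome_decays_value(self):
        p = SessionParameters(0.5, 2.0, 2.0, 0.0, 0.0, 0.0, 0.1)
        s = LatentState.zeros()
        s.Q[0, 1] = 1.0
        s = update_values(s, self.gw, Action.GO, 0, p)
        assert s.Q[0, 1] == pytest.approx(0.5)

    def test_zero_learning_rate_freezes_state(self):
        p = SessionParameters(1e-12, 2.0, 2.0, 0.0, 0.0, 0.0, 0.1)
        s = update_values(LatentState.zeros(), self.ngal, Action.NOGO, -1, p)
        assert np.allclose(s.Q, 0.0, atol=1e-10) and np.allclose(s.V, 0.0, atol=1e-10)

    def test_invalid_outcome_rejected(self):
        p = SessionParameters(0.5, 1.0, 1.0, 0.0, 0.0, 0.0, 0.1)
        with pytest.raises(ValueError):
            update_values(LatentState.zeros(), self.gw, Action.GO, 2, p)

    @given(
        st.floats(0.01, 0.99), st.floats(0.1, 5.0),
        st.floats(-3, 3), st.sampled_from([-1, 0, 1]),
    )
    @settings(max_examples=100, deadline=None)
    def test_update_is_contraction(self, eps, rho, q0, r):
        cond = condition_from_token("gw")
        p = SessionParameters(eps, rho, rho, 0.0, 0.0, 0.0, 0.1)
        s = LatentState.zeros()
        s.Q[0, 1] = q0
        s2 = update_values(s, cond, Action.GO, r, p)
        assert abs(s2.Q[0, 1] - rho * r) == pytest.approx((1 - eps) * abs(q0 - rho * r))


class TestActionWeights:
    def test_zero_state_gives_go_bias_only(self):
        p = SessionParameters(0.5, 1.0, 1.0, 0.7, 2.0, 2.0, 0.1)
        assert action_weights(LatentState.zeros(), condition_from_token("gw"), p) == (0.7, 0.0)

    def test_pavlovian_term_boosts_go_under_reward(self):
        p = SessionParameters(0.5, 1.0, 1.0, 0.0, 2.0, 2.0, 0.1)
        s = LatentState.zeros()
        s.V[0] = 0.5
        assert action_weights(s, condition_from_token("gw"), p)[0] == pytest.approx(1.0)

    def test_pavlovian_term_suppresses_go_under_punishment(self):
        p = SessionParameters(0.5, 1.0, 1.0, 0.0, 2.0, 2.0, 0.1)
        s = LatentState.zeros()
        s.V[2] = -0.5
        w_go, w_nogo = action_weights(s, condition_from_token("gal"), p)
        assert w_go == pytest.approx(-1.0) and w_nogo == 0.0


class TestChoiceProbability:
    def test_equal_weights_give_half(self):
        for xi in (0.0, 0.3, 1.0):
            assert choice_probability(2.0, 2.0, xi) == pytest.approx(0.5)

    def test_pure_noise_limit(self):
        assert choice_probability(10.0, -10.0, 1.0) == pytest.approx(0.5)

    def test_matches_logistic_oracle(self):
        assert choice_probability(1.0, 0.0, 0.0) == pytest.approx(0.731059, abs=1e-6)

    @given(st.floats(-30, 30), st.floats(-30, 30), st.floats(0.01, 0.99))
    @settings(max_examples=200, deadline=None)
    def test_noise_mixture_bounds(self, w_go, w_nogo, xi):
        p = choice_probability(w_go, w_nogo, xi)
        assert xi / 2 - 1e-12 <= p <= 1 - xi / 2 + 1e-12

    def test_non_finite_weights_rejected(self):
        with pytest.raises(ValueError):
            choice_probability(np.inf, 0.0, 0.1)


def _naive_session_loglik(trials, p):
    """Straight-line oracle: the four model equations composed literally."""
    Q = {(s, a): 0.0 for s in range(4) for a in range(2)}
    V = {s: 0.0 for s in range(4)}
    tok_idx = {"gw": 0, "ngw": 1, "gal": 2, "ngal": 3}
    ll = 0.0
    for t in trials:
        s = tok_idx[t.condition.token]
        win = s <= 1
        pi = p.pi_rew if win else p.pi_pun
        rho = p.rho_rew if win else p.rho_pun
        w_go = Q[(s, 1)] + p.go_bias + pi * V[s]
        w_nogo = Q[(s, 0)]
        p_go = (1 - p.xi) * math.exp(w_go) / (math.exp(w_go) + math.exp(w_nogo)) + p.xi / 2
        ll += math.log(p_go if t.response == Action.GO else 1 - p_go)
        a = int(t.response)
        Q[(s, a)] += p.eps * (rho * t.outcome - Q[(s, a)])
        V[s] += p.eps * (rho * t.outcome - V[s])
    return ll


class TestSessionLoglik:
    def test_single_trial_neutral_parameters(self):
        p = SessionParameters(0.5, 1.0, 1.0, 0.0, 0.0, 0.0, 1e-12)
        trials = simulate_session(p, TaskDesign(trials_per_condition=1), seed=0)[:1]
        assert session_loglik(trials, p) == pytest.approx(math.log(0.5))

    def test_matches_naive_oracle_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            eta = rng.normal(0, 1, 7)
            p = transform(eta)
            trials = simulate_session(p, TaskDesign(trials_per_condition=5), rng)
            assert session_loglik(trials, p) == pytest.approx(
                _naive_session_loglik(trials, p), abs=1e-9
            )

    def test_go_bias_monotone_for_all_go_sequence(self):
        base = simulate_session(
            SessionParameters(0.3, 2.0, 2.0, 3.0, 0.0, 0.0, 0.05),
            TaskDesign(trials_per_condition=5), seed=3,
        )
        all_go = [t for t in base if t.response == Action.GO]
        lls = [
            session_loglik(all_go, SessionParameters(0.3, 2.0, 2.0, b, 0.0, 0.0, 0.05))
            for b in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(b > a for a, b in zip(lls, lls[1:]))

    def test_unsorted_trials_rejected(self):
        p = SessionParameters(0.3, 2.0, 2.0, 0.0, 0.0, 0.0, 0.05)
        trials = simulate_session(p, TaskDesign(trials_per_condition=2), seed=1)
        with pytest.raises(ValueError):
            session_loglik(trials[::-1], p)


def _accuracy(trials, tokens):
    sel = [t for t in trials if t.condition.token in tokens]
    return np.mean([t.response == correct_action(t.condition) for t in sel])


class TestSimulateSession:
    def test_pure_noise_agent_goes_half_the_time(self):
        p = SessionParameters(0.3, 2.0, 2.0, 0.0, 0.0, 0.0, 1.0 - 1e-12)
        trials = simulate_session(p, seed=5)
        go_rate = np.mean([int(t.response) for t in trials])
        assert abs(go_rate - 0.5) < 0.12

    def test_reproducible_from_seed(self):
        p = SessionParameters(0.3, 2.0, 2.0, 0.5, 1.0, 1.0, 0.1)
        assert simulate_session(p, seed=9) == simulate_session(p, seed=9)

    def test_positive_pavlovian_bias_creates_congruency_advantage(self):
        p = SessionParameters(0.3, 3.0, 3.0, 0.0, 2.0, 2.0, 0.05)
        rng = np.random.default_rng(0)
        cong, incong = [], []
        for _ in range(100):
            trials = simulate_session(p, seed=rng)
            cong.append(_accuracy(trials, {"gw", "ngal"}))
            incong.append(_accuracy(trials, {"ngw", "gal"}))
        assert np.mean(cong) > np.mean(incong) + 0.05

    def test_no_bias_symmetric_accuracy_within_valence(self):
        # without Pavlovian or go bias the model is invariant to swapping
        # action labels, so go-win and no-go-win accuracies (and likewise
        # the two avoid conditions) are exchangeable.  Across valences no
        # such symmetry exists: correct avoidance earns r=0, which carries
        # no learning signal relative to zero-initialized values.
        p = SessionParameters(0.3, 2.0, 2.0, 0.0, 0.0, 0.0, 0.05)
        rng = np.random.default_rng(1)
        acc = {tok: [] for tok in ("gw", "ngw", "gal", "ngal")}
        for _ in range(100):
            trials = simulate_session(p, seed=rng)
            for tok in acc:
                acc[tok].append(_accuracy(trials, {tok}))
        assert ttest_ind(acc["gw"], acc["ngw"]).pvalue > 0.01
        assert ttest_ind(acc["gal"], acc["ngal"]).pvalue > 0.01
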
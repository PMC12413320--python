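"""Update rules, softmax, and sequence likelihoods against hand computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from revlearn.models import (
    MODELS,
    ValueState,
    choice_prob,
    evaluate_blocks,
    get_model,
    initial_state,
    sequence_loglik,
    update_ewa,
    update_ewa_2lr,
    update_fictitious,
    update_rw_pn,
)


class TestUpdateRules:
    def test_rw_pn_hand_values(self):
        s = initial_state()
        s = update_rw_pn(s, 0, +1, eta_rew=1.0, eta_nrew=0.2)
        assert s.V[0] == pytest.approx(1.0)  # full update to the outcome
        s2 = ValueState(V=[0.5, 0.0])
        s2 = update_rw_pn(s2, 0, -1, eta_rew=1.0, eta_nrew=0.2)
        assert s2.V[0] == pytest.approx(0.5 + 0.2 * (-1.5))  # = 0.2
        # zero rates leave the state untouched
        s3 = ValueState(V=[0.3, -0.4])
        for o in (+1, -1):
            out = update_rw_pn(s3, 1, o, 0.0, 0.0)
            assert np.allclose(out.V, s3.V)

    def test_rw_pn_only_chosen_updated(self):
        s = ValueState(V=[0.3, -0.4])
        out = update_rw_pn(s, 0, +1, 0.5, 0.5)
        assert out.V[1] == s.V[1]

    def test_outcome_zero_rejected(self):
        for fn in (update_rw_pn, update_fictitious):
            with pytest.raises(ValueError, match="coding"):
                fn(initial_state(), 0, 0, 0.5, 0.5)

    def test_ewa_running_mean(self):
        # rho=1, phi=1 from V=0, n=1: values follow a running mean with a
        # prior pseudo-observation of 0
        s = initial_state()
        s = update_ewa(s, 0, +1, rho=1.0, phi=1.0)
        assert s.V[0] == pytest.approx(0.5)
        assert s.n[0] == pytest.approx(2.0)
        s = update_ewa(s, 0, +1, rho=1.0, phi=1.0)
        assert s.V[0] == pytest.approx(2.0 / 3.0)

    def test_ewa_rho_zero_resets_experience(self):
        s = initial_state()
        for _ in range(5):
            s = update_ewa(s, 0, +1, rho=0.0, phi=0.3)
            assert s.n[0] == pytest.approx(1.0)

    def test_ewa_collapses_to_outcome(self):
        s = ValueState(V=[0.7, 0.0])
        for o in (+1, -1):
            out = update_ewa(s, 0, o, rho=0.0, phi=0.0)
            assert out.V[0] == pytest.approx(o)

    def test_ewa_2lr_matches_ewa_when_rates_equal(self):
        rng = np.random.default_rng(1)
        s1, s2 = initial_state(), initial_state()
        for _ in range(20):
            c = int(rng.integers(2))
            o = int(rng.choice([-1, 1]))
            s1 = update_ewa(s1, c, o, rho=0.6, phi=0.4)
            s2 = update_ewa_2lr(s2, c, o, rho=0.6, phi_rew=0.4, phi_nrew=0.4)
            assert np.allclose(s1.V, s2.V) and np.allclose(s1.n, s2.n)

    def test_ewa_2lr_negative_branch_hand_value(self):
        s = ValueState(V=[0.5, 0.0], n=[2.0, 1.0])
        out = update_ewa_2lr(s, 0, -1, rho=1.0, phi_rew=0.9, phi_nrew=0.0)
        # n: 2*1+1=3; V = (0.5*0*2 + (-1))/3
        assert out.V[0] == pytest.approx(-1.0 / 3.0)
        assert out.n[0] == pytest.approx(3.0)

    def test_fictitious_hand_values(self):
        s = initial_state()
        out = update_fictitious(s, 0, +1, eta_rew=0.5, eta_nrew=0.25)
        assert out.V[0] == pytest.approx(0.5)
        assert out.V[1] == pytest.approx(-0.25)

    def test_fictitious_mirror_symmetry(self):
        # equal rates from zero values: the unchosen value is always the
        # negation of the chosen one
        rng = np.random.default_rng(5)
        s = initial_state()
        for _ in range(30):
            c = int(rng.integers(2))
            o = int(rng.choice([-1, 1]))
            s = update_fictitious(s, c, o, 0.37, 0.37)
            assert s.V[1] == pytest.approx(-s.V[0])

    def test_fictitious_zero_rates_no_change(self):
        s = ValueState(V=[0.2, -0.1])
        out = update_fictitious(s, 1, -1, 0.0, 0.0)
        assert np.allclose(out.V, s.V)


class TestChoiceProb:
    def test_symmetry_and_flat_beta(self):
        assert choice_prob(0.3, 0.3, 5.0) == pytest.approx(0.5)
        assert choice_prob(2.0, -1.0, 0.0) == pytest.approx(0.5)

    def test_logistic_value(self):
        assert choice_prob(1.0, 0.0, 2.0) == pytest.approx(0.88080, abs=1e-5)

    def test_extreme_arguments_stable(self):
        assert choice_prob(1e3, -1e3, 1e3) == pytest.approx(1.0)
        assert choice_prob(-1e3, 1e3, 1e3) == pytest.approx(0.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            choice_prob(0.0, 0.0, -1.0)

    @given(
        dv=st.floats(-3, 3),
        b1=st.floats(0, 10),
        b2=st.floats(0, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_beta(self, dv, b1, b2):
        # raising beta weakly increases the probability of the higher-valued
        # option
        lo, hi = sorted([b1, b2])
        p_lo = choice_prob(dv, 0.0, lo)
        p_hi = choice_prob(dv, 0.0, hi)
        if dv >= 0:
            assert p_hi >= p_lo - 1e-12
        else:
            assert p_hi <= p_lo + 1e-12


class TestSequenceLoglik:
    def test_flat_agent(self):
        ch = [0, 1] * 14
        oc = [1, -1] * 14
        ll = sequence_loglik(
            "fictitious", dict(eta_rew=0.5, eta_nrew=0.5, beta=0.0), ch, oc
        )
        assert ll == pytest.approx(28 * math.log(0.5))

    def test_three_trial_hand_oracle(self):
        # independent step-by-step evaluation of the fictitious model
        er, en, beta = 0.5, 0.25, 1.0
        choices, outcomes = [0, 0, 1], [1, -1, 1]
        V = [0.0, 0.0]
        expected = 0.0
        for c, o in zip(choices, outcomes):
            expected += math.log(expit(beta * (V[c] - V[1 - c])))
            if o > 0:
                V[c] += er * (o - V[c])
                V[1 - c] += en * (-o - V[1 - c])
            else:
                V[c] += en * (o - V[c])
                V[1 - c] += er * (-o - V[1 - c])
        got = sequence_loglik(
            "fictitious", dict(eta_rew=er, eta_nrew=en, beta=beta), choices, outcomes
        )
        assert got == pytest.approx(expected)

    def test_per_trial_sums_to_total(self):
        rng = np.random.default_rng(2)
        ch = rng.integers(0, 2, 28).tolist()
        oc = rng.choice([-1, 1], 28).tolist()
        total, pt = sequence_loglik(
            "ewa", dict(rho=0.5, phi=0.7, beta=2.0), ch, oc, per_trial=True
        )
        assert pt.sum() == pytest.approx(total)
        assert np.all(pt <= 0)  # each trial's log-probability is <= log(1)

    def test_missing_trials_skipped(self):
        ch = [0, -1, 1]
        oc = [1, 1, -1]
        ll = sequence_loglik(
            "rw_pn", dict(eta_rew=0.3, eta_nrew=0.3, beta=1.5), ch, oc
        )
        # removing the missing trial changes nothing: no update, no term
        ll2 = sequence_loglik(
            "rw_pn", dict(eta_rew=0.3, eta_nrew=0.3, beta=1.5), [0, 1], [1, -1]
        )
        assert ll == pytest.approx(ll2)

    def test_nan_params_rejected(self):
        with pytest.raises(ValueError):
            sequence_loglik(
                "rw_pn", dict(eta_rew=float("nan"), eta_nrew=0.1, beta=1.0),
                [0], [1],
            )

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            get_model("q_learning")

    def test_rw_pn_equal_rates_is_classic_rescorla_wagner(self):
        # single-rate delta rule computed inline as the oracle
        rng = np.random.default_rng(7)
        ch = rng.integers(0, 2, 40)
        oc = rng.choice([-1.0, 1.0], 40)
        eta, beta = 0.35, 2.0
        V = np.zeros(2)
        expected = 0.0
        for c, o in zip(ch, oc):
            expected += math.log(expit(beta * (V[c] - V[1 - c])))
            V[c] += eta * (o - V[c])
        got = sequence_loglik(
            "rw_pn", dict(eta_rew=eta, eta_nrew=eta, beta=beta), ch, oc
        )
        assert got == pytest.approx(expected)


class TestEvaluateBlocks:
    @pytest.mark.parametrize("name", sorted(MODELS))
    def test_engines_agree(self, name):
        rng = np.random.default_rng(11)
        spec = get_model(name)
        B, T = 17, 28
        ch = rng.integers(0, 2, (B, T))
        ch[rng.random((B, T)) < 0.05] = -1
        oc = rng.choice([-1.0, 1.0], (B, T))
        params = {
            k: (rng.uniform(0.05, 0.95, B) if k != "beta" else rng.uniform(0, 8, B))
            for k in spec.params
        }
        a = evaluate_blocks(spec, params, ch, oc, per_trial=True, grad=True,
                            engine="numpy")
        b = evaluate_blocks(spec, params, ch, oc, per_trial=True, grad=True,
                            engine="numba")
        for key in ("loglik", "pointwise", "grad"):
            np.testing.assert_allclose(a[key], b[key], atol=1e-12)

    @pytest.mark.parametrize("name", sorted(MODELS))
    def test_gradient_matches_finite_differences(self, name):
        rng = np.random.default_rng(13)
        spec = get_model(name)
        B, T = 6, 15
        ch = rng.integers(0, 2, (B, T))
        oc = rng.choice([-1.0, 1.0], (B, T))
        params = {
            k: (rng.uniform(0.1, 0.9, B) if k != "beta" else rng.uniform(0.5, 5, B))
            for k in spec.params
        }
        out = evaluate_blocks(spec, params, ch, oc, grad=True)
        eps = 1e-6
        for j, k in enumerate(spec.params):
            bumped = {kk: vv.copy() for kk, vv in params.items()}
            bumped[k] = bumped[k] + eps
            num = (evaluate_blocks(spec, bumped, ch, oc)["loglik"]
                   - out["loglik"]) / eps
            np.testing.assert_allclose(out["grad"][:, j], num, atol=2e-4)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_value_bounded_for_delta_rule_models(self, seed):
        # with outcomes in {-1, +1} and rates in [0, 1] the values of the
        # delta-rule models never leave [-1, 1]
        rng = np.random.default_rng(seed)
        ch = rng.integers(0, 2, 60)
        oc = rng.choice([-1, 1], 60)
        for name in ("rw_pn", "fictitious"):
            from revlearn.models import apply_update, initial_state

            params = dict(
                eta_rew=rng.uniform(0, 1), eta_nrew=rng.uniform(0, 1), beta=1.0
            )
            s = initial_state()
            for c, o in zip(ch, oc):
                s = apply_update(name, s, int(c), int(o), params)
                assert np.all(np.abs(s.V) <= 1 + 1e-12)
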
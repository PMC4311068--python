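"""Rescorla-Wagner observation model: softmax, updates, likelihood, gradient."""

import math

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st

from stressrl import rw, task
from stressrl.task import TaskConfig

finite = st.floats(-50, 50, allow_nan=False)


def test_softmax_examples():
    np.testing.assert_allclose(rw.softmax_prob([0.0, 0.0]), [0.5, 0.5])
    np.testing.assert_allclose(
        rw.softmax_prob([1.0, 0.0]), [0.7310586, 0.2689414], atol=1e-7
    )
    with pytest.raises(ValueError):
        rw.softmax_prob([np.nan, 0.0])


@given(q0=finite, q1=finite, c=finite)
@settings(max_examples=200, deadline=None)
def test_softmax_properties(q0, q1, c):
    """Normalization, order preservation, and shift invariance."""
    p = rw.softmax_prob([q0, q1])
    assert p.sum() == pytest.approx(1.0)
    assert np.all(p >= 0) and np.all(p <= 1)
    if q0 - q1 > 1e-9:  # strict order only where floats can resolve it
        assert p[0] > p[1]
    np.testing.assert_allclose(rw.softmax_prob([q0 + c, q1 + c]), p, atol=1e-12)


@pytest.mark.parametrize(
    "q,r,eps,expected",
    [
        (0.0, 2.73, 1.0, 2.73),      # full update jumps straight to R
        (5.0, 5.0, 0.5, 5.0),        # zero prediction error is a fixed point
        (0.0, -0.84, 0.62, -0.5208),
        (1.0, 0.0, 0.25, 0.75),
    ],
)
def test_value_update(q, r, eps, expected):
    assert rw.update_value(q, r, eps) == pytest.approx(expected)


def test_value_update_rejects_bad_learning_rate():
    with pytest.raises(ValueError):
        rw.update_value(0.0, 1.0, 1.5)
    with pytest.raises(ValueError):
        rw.update_value(0.0, 1.0, -0.1)


def test_effective_reinforcement(median_params):
    assert rw.effective_reinforcement(task.REWARD, median_params) == pytest.approx(2.73)
    assert rw.effective_reinforcement(task.PUNISHMENT, median_params) == pytest.approx(-0.84)
    zero = rw.AgentParams(0.5, 1.0, 0.0)
    assert rw.effective_reinforcement(task.PUNISHMENT, zero) == 0.0
    with pytest.raises(ValueError):
        rw.effective_reinforcement(0, median_params)


@given(
    eps=st.floats(0.01, 0.99),
    b=st.floats(1e-3, 0.5),
    p=st.floats(1e-3, 0.5),
)
@settings(max_examples=100, deadline=None)
def test_transform_round_trip(eps, b, p):
    params = rw.AgentParams(eps, b, p)
    back = rw.from_theta(rw.to_theta(params))
    assert back.epsilon == pytest.approx(eps, abs=1e-12)
    assert back.beta_rew == pytest.approx(b, rel=1e-12)
    assert back.beta_pun == pytest.approx(p, rel=1e-12)


def test_zero_sensitivity_loglik_is_n_log_half():
    """With beta_rew = beta_pun = 0 the values never move, so every choice
    has probability exactly 1/2."""
    actions = np.array([0, 1, 1, 0, 1, 0, 0, 1])
    outcomes = np.array([1, -1, 1, 1, -1, -1, 1, 1])
    ll, trace = rw.sequence_loglik(
        (actions, outcomes), rw.AgentParams(0.7, 0.0, 0.0)
    )
    assert ll == len(actions) * math.log(0.5)
    assert np.all(trace.pe == 0)


def test_three_trial_likelihood_matches_hand_recursion():
    """Actions L,R,L with outcomes +,-,+ at eps=0.5, beta=1: stepping the
    recursion by hand gives Q traces (0,0)->(0.5,0)->(0.5,-0.5) and
    ll = ln(.5) + ln(1/(1+e^0.5)) + ln(1/(1+e^-1))."""
    actions = np.array([0, 1, 0])
    outcomes = np.array([1, -1, 1])
    ll, trace = rw.sequence_loglik(
        (actions, outcomes), rw.AgentParams(0.5, 1.0, 1.0)
    )
    assert ll == pytest.approx(-1.980485852, abs=1e-8)
    np.testing.assert_allclose(trace.pe, [1.0, -1.0, 0.5])
    np.testing.assert_allclose(trace.q_values, [[0, 0], [0.5, 0], [0.5, -0.5]])
    np.testing.assert_allclose(trace.effective_reinforcement, [1.0, -1.0, 1.0])
    # bit-identical on recomputation
    assert rw.sequence_loglik((actions, outcomes), rw.AgentParams(0.5, 1.0, 1.0))[0] == ll


def test_loglik_rejects_empty_sequence(median_params):
    with pytest.raises(ValueError):
        rw.sequence_loglik((np.array([]), np.array([])), median_params)


def test_pe_update_consistency(median_agent_events, median_params):
    """Q_t(chosen) - Q_{t-1}(chosen) == eps * PE_t on every trial."""
    _, tr = rw.sequence_loglik(median_agent_events, median_params)
    actions, _ = rw.actions_outcomes(median_agent_events)
    q_after = tr.q_values[1:]  # pre-trial values of t+1 are post-update of t
    for t in range(len(actions) - 1):
        a = actions[t]
        delta = q_after[t, a] - tr.q_values[t, a]
        assert delta == pytest.approx(median_params.epsilon * tr.pe[t], abs=1e-12)
        # the unchosen action's value is untouched
        assert q_after[t, 1 - a] == tr.q_values[t, 1 - a]


def test_analytic_gradient_matches_finite_differences(median_agent_events):
    a, o = rw.actions_outcomes(median_agent_events)
    for theta in ([0.3, 0.8, -0.2], [-1.0, 0.1, 0.5], [1.5, 1.6, -1.0]):
        theta = np.array(theta)
        _, g = rw.loglik_and_grad(a, o, theta)
        g_num = scipy.optimize.approx_fprime(
            theta, lambda t: rw.loglik_and_grad(a, o, t)[0], 1e-6
        )
        np.testing.assert_allclose(g, g_num, rtol=1e-4, atol=1e-5)


def test_pe_trace_tsv_round_trip(tmp_path, median_agent_events, median_params):
    _, tr = rw.sequence_loglik(median_agent_events, median_params)
    p = tmp_path / "pe.tsv"
    tr.write(p)
    back = rw.PETrace.read(p)
    np.testing.assert_allclose(back.pe, tr.pe, rtol=1e-9)
    np.testing.assert_allclose(back.q_values, tr.q_values, rtol=1e-9)


def test_indifferent_agent_chooses_uniformly(default_cfg):
    ev = rw.simulate_agent(
        rw.AgentParams(0.5, 0.0, 0.0), default_cfg, np.random.default_rng(3)
    )
    frac_left = (ev["action"] == task.ACTION_LEFT).mean()
    assert abs(frac_left - 0.5) < 4 * np.sqrt(0.25 / len(ev))


def test_greedy_agent_saturates_on_single_block():
    """With a very high reward sensitivity the softmax saturates and the
    agent locks onto the 0.8-probability action."""
    cfg = TaskConfig(n_trials_total=100, n_trials_per_session=100)
    agent = rw.RWAgent(rw.AgentParams(0.5, 20.0, 0.0))
    ev = task.run_session(agent, cfg, np.random.default_rng(8),
                          block_sequence=["80/20"] * 30)
    late = ev.iloc[50:]
    assert (late["action"] == task.ACTION_LEFT).mean() > 0.9


def test_generating_parameters_beat_perturbed_on_average(default_cfg, median_params):
    """The likelihood of the generating parameters exceeds that of strongly
    perturbed parameters on long sequences (averaged over seeds)."""
    perturbed = rw.AgentParams(0.05, 8.0, 4.0)
    diffs = []
    for seed in range(5):
        ev = rw.simulate_agent(median_params, default_cfg, np.random.default_rng(seed))
        diffs.append(
            rw.sequence_loglik(ev, median_params)[0]
            - rw.sequence_loglik(ev, perturbed)[0]
        )
    assert np.mean(diffs) > 0


def test_agent_params_validation():
    with pytest.raises(ValueError):
        rw.AgentParams(1.2, 1.0, 1.0)
    with pytest.raises(ValueError):
        rw.AgentParams(0.5, -1.0, 1.0)
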
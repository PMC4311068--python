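"""Rescorla-Wagner / softmax observation model.

The agent tracks an expected value Q(a) per action. The chosen action's value
is updated by a fraction eps of the reward prediction error,

    Q_t(a_t) = Q_{t-1}(a_t) + eps * (R_t - Q_{t-1}(a_t)),
    PE_t     = R_t - Q_{t-1}(a_t),

where the effective reinforcement R_t is +beta_rew after a reward and
-beta_pun after a punishment, so the sensitivities both scale the feedback
and set choice determinism through the softmax

    p(a | Q) = exp(Q(a)) / sum_a' exp(Q(a')).

Parameters are estimated in an unconstrained space theta =
(logit eps, log beta_rew, log beta_pun); this module also supplies the exact
gradient of the choice log-likelihood in that space, obtained by propagating
dQ/dtheta through the update recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import task
from .task import REWARD, PUNISHMENT, TaskConfig

__all__ = [
    "AgentParams", "PETrace", "softmax_prob", "update_value",
    "effective_reinforcement", "sequence_loglik", "loglik_and_grad",
    "to_theta", "from_theta", "RWAgent", "simulate_agent", "actions_outcomes",
]


@dataclass(frozen=True)
class AgentParams:
    """Natural-space parameters: learning rate and feedback sensitivities."""

    epsilon: float
    beta_rew: float
    beta_pun: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.beta_rew < 0 or self.beta_pun < 0:
            raise ValueError("sensitivities must be non-negative")
        for v in (self.epsilon, self.beta_rew, self.beta_pun):
            if not math.isfinite(v):
                raise ValueError("parameters must be finite")


def to_theta(params: AgentParams) -> np.ndarray:
    """Map to the unconstrained space (logit eps, log b_rew, log b_pun)."""
    eps = min(max(params.epsilon, 1e-12), 1 - 1e-12)
    return np.array([
        math.log(eps / (1.0 - eps)),
        math.log(max(params.beta_rew, 1e-300)),
        math.log(max(params.beta_pun, 1e-300)),
    ])


def from_theta(theta: np.ndarray) -> AgentParams:
    """Inverse of :func:`to_theta` (sigmoid / exp)."""
    t = np.asarray(theta, dtype=float)
    return AgentParams(
        epsilon=1.0 / (1.0 + math.exp(-t[0])),
        beta_rew=math.exp(t[1]),
        beta_pun=math.exp(t[2]),
    )


def softmax_prob(q) -> np.ndarray:
    """Softmax choice probabilities over the two action values."""
    q = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("action values must be finite")
    z = q - q.max()
    e = np.exp(z)
    return e / e.sum()


def update_value(q_chosen: float, r: float, epsilon: float) -> float:
    """Delta-rule update of the chosen action's value."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must lie in [0, 1], got {epsilon}")
    return q_chosen + epsilon * (r - q_chosen)


def effective_reinforcement(outcome: int, params: AgentParams) -> float:
    """+beta_rew after reward, -beta_pun after punishment."""
    if outcome == REWARD:
        return params.beta_rew
    if outcome == PUNISHMENT:
        return -params.beta_pun
    raise ValueError(f"unknown outcome code {outcome!r}")


@dataclass
class PETrace:
    """Trial-wise model quantities at fixed parameters.

    ``q_values[t]`` holds both action values *before* the trial-t update, so
    ``pe[t] == effective_reinforcement[t] - q_values[t, action_t]``.
    """

    q_values: np.ndarray          # (n, 2)
    pe: np.ndarray                # (n,)
    effective_reinforcement: np.ndarray  # (n,)

    def __len__(self) -> int:
        return len(self.pe)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(len(self.pe)),
            "q_left": self.q_values[:, 0],
            "q_right": self.q_values[:, 1],
            "r_eff": self.effective_reinforcement,
            "pe": self.pe,
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "PETrace":
        df = pd.read_csv(path, sep="\t")
        return cls(
            q_values=df[["q_left", "q_right"]].to_numpy(),
            pe=df["pe"].to_numpy(),
            effective_reinforcement=df["r_eff"].to_numpy(),
        )


def actions_outcomes(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract integer action (0/1) and outcome (+1/-1) arrays from an event table."""
    a = events["action"]
    if a.dtype == object:
        a = a.map(task.ACTION_FROM_CODE)
    return a.to_numpy(dtype=int), events["outcome"].to_numpy(dtype=int)


def _log_sigmoid(x: float) -> float:
    # log(1 / (1 + e^-x)), stable for both signs
    if x >= 0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


def sequence_loglik(
    events, params: AgentParams, q0: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, PETrace]:
    """Choice log-likelihood of an event sequence, plus the PE trace.

    Values start at ``q0`` (default (0, 0)) and are updated trial by trial;
    the log-likelihood is the sum of log softmax probabilities of the chosen
    actions. Returns ``(loglik, trace)``.
    """
    if isinstance(events, pd.DataFrame):
        actions, outcomes = actions_outcomes(events)
    else:
        actions, outcomes = events
        actions = np.asarray(actions, dtype=int)
        outcomes = np.asarray(outcomes, dtype=int)
    n = len(actions)
    if n == 0:
        raise ValueError("event sequence is empty")
    eps, brew, bpun = params.epsilon, params.beta_rew, params.beta_pun
    q = [float(q0[0]), float(q0[1])]
    qs = np.empty((n, 2))
    pes = np.empty(n)
    rs = np.empty(n)
    ll = 0.0
    for t in range(n):
        a = actions[t]
        qs[t, 0], qs[t, 1] = q[0], q[1]
        ll += _log_sigmoid(q[a] - q[1 - a])
        r = brew if outcomes[t] == REWARD else -bpun
        rs[t] = r
        pes[t] = r - q[a]
        q[a] += eps * pes[t]
    return ll, PETrace(q_values=qs, pe=pes, effective_reinforcement=rs)


def loglik_and_grad(
    actions: np.ndarray, outcomes: np.ndarray, theta: np.ndarray
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its exact gradient in transformed space.

    dQ/d(eps, b_rew, b_pun) is propagated through the delta-rule recursion
    (for the chosen action c: dQ'[c] = (1-eps) dQ[c] + d(eps*(R-Q[c]))), and
    chained onto theta via d eps/d eps' = eps(1-eps), d beta/d beta' = beta.
    """
    # clamp the unconstrained parameters to a huge-but-safe range so line
    # searches through extreme trial points cannot overflow exp()
    t0, t1, t2 = (min(max(float(v), -50.0), 50.0) for v in theta[:3])
    eps = 1.0 / (1.0 + math.exp(-t0))
    brew = math.exp(t1)
    bpun = math.exp(t2)
    q = [0.0, 0.0]
    # per-action derivatives of Q wrt (eps, brew, bpun)
    ge = [0.0, 0.0]
    gr = [0.0, 0.0]
    gp = [0.0, 0.0]
    ll = 0.0
    de = dr = dp = 0.0  # gradient accumulators (natural space)
    for t in range(len(actions)):
        a = int(actions[t])
        u = 1 - a
        x = q[a] - q[u]
        ll += _log_sigmoid(x)
        # d ll_t / dQ(a) = 1 - p(a);  d ll_t / dQ(u) = -(1 - p(a))
        if x >= 0:  # w = 1 - p(a) = sigmoid(-x), overflow-safe both ways
            ex = math.exp(-x)
            w = ex / (1.0 + ex)
        else:
            w = 1.0 / (1.0 + math.exp(x))
        de += w * (ge[a] - ge[u])
        dr += w * (gr[a] - gr[u])
        dp += w * (gp[a] - gp[u])
        if outcomes[t] == REWARD:
            r, drdr, drdp = brew, 1.0, 0.0
        else:
            r, drdr, drdp = -bpun, 0.0, -1.0
        pe = r - q[a]
        ge[a] = (1.0 - eps) * ge[a] + pe
        gr[a] = (1.0 - eps) * gr[a] + eps * drdr
        gp[a] = (1.0 - eps) * gp[a] + eps * drdp
        q[a] += eps * pe
    grad = np.array([de * eps * (1.0 - eps), dr * brew, dp * bpun])
    return ll, grad


class RWAgent:
    """Generative softmax/RW agent usable with :func:`stressrl.task.run_session`."""

    def __init__(self, params: AgentParams, q0: tuple[float, float] = (0.0, 0.0)):
        self.params = params
        self._q0 = q0
        self.q = np.array(q0, dtype=float)

    def reset(self) -> None:
        self.q = np.array(self._q0, dtype=float)

    def choose(self, rng: np.random.Generator) -> int:
        p_left = softmax_prob(self.q)[0]
        return task.ACTION_LEFT if rng.random() < p_left else task.ACTION_RIGHT

    def observe(self, action: int, outcome: int) -> None:
        r = effective_reinforcement(outcome, self.params)
        self.q[action] = update_value(self.q[action], r, self.params.epsilon)


def simulate_agent(
    params: AgentParams,
    cfg: TaskConfig,
    rng: np.random.Generator,
    carry_values: bool = True,
) -> pd.DataFrame:
    """Simulate one subject playing the full protocol; returns the event table.

    ``carry_values=False`` resets Q to the starting values between sessions.
    """
    agent = RWAgent(params)
    return task.simulate_subject(
        agent, cfg, rng, reset_agent_between_sessions=not carry_values
    )
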
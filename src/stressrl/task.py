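"""Probabilistic reversal-learning task environment.

Two-session task (100 trials each). On every trial the agent picks the left
or right target and receives probabilistic reward or punishment feedback.
Reward contingencies come in three block types — 20/80, 80/20 and 50/50
(probability of reward for the left / right response) — and the active block
switches covertly once the agent has done at least ``min_block_trials``
trials in the block with at least ``criterion_correct_frac`` of them correct,
or automatically after ``max_block_trials`` trials.

The event table produced here (one row per trial) is the behavioral unit
every downstream stage consumes: model fitting reads ``action``/``outcome``,
the fMRI design builder reads feedback ``onset_s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

ACTION_LEFT = 0
ACTION_RIGHT = 1
#: TSV dialect: actions coded L/R, outcomes +1 (reward) / -1 (punishment)
ACTION_CODES = {ACTION_LEFT: "L", ACTION_RIGHT: "R"}
ACTION_FROM_CODE = {"L": ACTION_LEFT, "R": ACTION_RIGHT}
REWARD = 1
PUNISHMENT = -1

EVENT_COLUMNS = [
    "trial", "session", "block_id", "block_type",
    "action", "outcome", "onset_s", "reached_criterion",
]


@dataclass(frozen=True)
class BlockType:
    """One reward-allocation regime: P(reward) for the left/right response."""

    reward_prob_left: float
    reward_prob_right: float
    label: str

    def reward_prob(self, action: int) -> float:
        return (self.reward_prob_left, self.reward_prob_right)[action]

    @property
    def better_action(self) -> int | None:
        """Higher-reward-probability action, or None in a 50/50 block."""
        if self.reward_prob_left == self.reward_prob_right:
            return None
        return ACTION_LEFT if self.reward_prob_left > self.reward_prob_right else ACTION_RIGHT


BLOCK_TYPES: dict[str, BlockType] = {
    "20/80": BlockType(0.2, 0.8, "20/80"),
    "80/20": BlockType(0.8, 0.2, "80/20"),
    "50/50": BlockType(0.5, 0.5, "50/50"),
}


@dataclass
class TaskConfig:
    """Task schedule and timing parameters.

    ``criterion_rule`` decides what counts as a "correct" response for the
    block-switching criterion: ``"better_action"`` scores asymmetric-block
    trials by whether the 0.8-probability target was chosen and 50/50 trials
    by whether they were rewarded; ``"rewarded"`` scores every trial by
    feedback alone.
    """

    n_trials_total: int = 200
    n_trials_per_session: int = 100
    min_block_trials: int = 10
    criterion_correct_frac: float = 0.70
    max_block_trials: int = 16
    iti_range_s: tuple[float, float] = (1.0, 6.5)
    feedback_duration_s: float = 1.0
    max_rt_s: float = 2.0
    first_onset_s: float = 2.0
    criterion_rule: str = "better_action"

    def __post_init__(self) -> None:
        if self.min_block_trials > self.max_block_trials:
            raise ValueError("min_block_trials must be <= max_block_trials")
        if not 0.0 < self.criterion_correct_frac < 1.0:
            raise ValueError("criterion_correct_frac must lie in (0, 1)")
        if self.criterion_rule not in ("better_action", "rewarded"):
            raise ValueError(f"unknown criterion_rule {self.criterion_rule!r}")
        if self.n_trials_total % self.n_trials_per_session:
            raise ValueError("n_trials_total must be a multiple of n_trials_per_session")

    @property
    def n_sessions(self) -> int:
        return self.n_trials_total // self.n_trials_per_session


class Agent(Protocol):
    """Minimal interface the task loop drives."""

    def choose(self, rng: np.random.Generator) -> int: ...

    def observe(self, action: int, outcome: int) -> None: ...


class RandomAgent:
    """Uniform-random policy; never learns."""

    def choose(self, rng: np.random.Generator) -> int:
        return int(rng.integers(2))

    def observe(self, action: int, outcome: int) -> None:
        pass


class FixedActionAgent:
    """Always presses the same button (used for schedule bookkeeping tests)."""

    def __init__(self, action: int):
        self.action = action

    def choose(self, rng: np.random.Generator) -> int:
        return self.action

    def observe(self, action: int, outcome: int) -> None:
        pass


def sample_outcome(block: BlockType, action: int, rng: np.random.Generator) -> int:
    """Draw reward (+1) or punishment (-1) feedback for ``action`` in ``block``."""
    if action not in (ACTION_LEFT, ACTION_RIGHT):
        raise ValueError(f"invalid action {action!r}")
    return REWARD if rng.random() < block.reward_prob(action) else PUNISHMENT


def should_switch_block(n_block_trials: int, n_block_correct: int, cfg: TaskConfig) -> bool:
    """Block-switch rule: criterion reached, or the trial cap exhausted."""
    if n_block_trials < 0 or n_block_correct < 0:
        raise ValueError("trial and correct counts must be non-negative")
    if n_block_correct > n_block_trials:
        raise ValueError("n_block_correct cannot exceed n_block_trials")
    if n_block_trials >= cfg.max_block_trials:
        return True
    return (
        n_block_trials >= cfg.min_block_trials
        and n_block_correct / n_block_trials >= cfg.criterion_correct_frac
    )


def is_criterion_correct(block: BlockType, action: int, outcome: int, rule: str) -> bool:
    if rule == "rewarded":
        return outcome == REWARD
    better = block.better_action
    if better is None:  # 50/50: no better option, fall back to feedback
        return outcome == REWARD
    return action == better


def _draw_block(current: str | None, rng: np.random.Generator) -> str:
    labels = sorted(BLOCK_TYPES)
    if current is not None:
        labels = [lb for lb in labels if lb != current]
    return labels[rng.integers(len(labels))]


def run_session(
    agent: Agent,
    cfg: TaskConfig,
    rng: np.random.Generator,
    session: int = 1,
    start_block_id: int = 0,
    start_trial: int = 0,
    block_sequence: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run one scanning session and return its event table.

    Onsets are feedback onsets in seconds from the session start. If
    ``block_sequence`` is given, block types are taken from it in order
    instead of being drawn randomly (the sequence must be long enough).
    """
    seq = iter(block_sequence) if block_sequence is not None else None

    def next_block(current: str | None) -> BlockType:
        label = next(seq) if seq is not None else _draw_block(current, rng)
        return BLOCK_TYPES[label]

    rows: list[dict] = []
    block = next_block(None)
    block_id = start_block_id
    n_block, n_correct = 0, 0
    t = cfg.first_onset_s

    for i in range(cfg.n_trials_per_session):
        action = agent.choose(rng)
        if action not in (ACTION_LEFT, ACTION_RIGHT):
            raise ValueError(f"agent returned invalid action {action!r}")
        outcome = sample_outcome(block, action, rng)
        agent.observe(action, outcome)
        n_block += 1
        n_correct += is_criterion_correct(block, action, outcome, cfg.criterion_rule)
        rows.append({
            "trial": start_trial + i,
            "session": session,
            "block_id": block_id,
            "block_type": block.label,
            "action": action,
            "outcome": outcome,
            "onset_s": t,
            "reached_criterion": False,
        })
        t += cfg.feedback_duration_s + rng.uniform(*cfg.iti_range_s)
        if should_switch_block(n_block, n_correct, cfg):
            hit = n_correct / n_block >= cfg.criterion_correct_frac and n_block >= cfg.min_block_trials
            rows[-1]["reached_criterion"] = bool(hit)
            block = next_block(block.label)
            block_id += 1
            n_block, n_correct = 0, 0
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def simulate_subject(
    agent: Agent,
    cfg: TaskConfig,
    rng: np.random.Generator,
    reset_agent_between_sessions: bool = False,
) -> pd.DataFrame:
    """Run the full protocol (all sessions); block ids continue across sessions.

    A fresh block starts at each session boundary (sessions are separate
    scanner runs), but the agent's internal state carries over unless
    ``reset_agent_between_sessions`` is set.
    """
    frames = []
    block_id = 0
    trial0 = 0
    for sess in range(1, cfg.n_sessions + 1):
        if sess > 1 and reset_agent_between_sessions and hasattr(agent, "reset"):
            agent.reset()
        df = run_session(agent, cfg, rng, session=sess,
                         start_block_id=block_id, start_trial=trial0)
        block_id = int(df["block_id"].max()) + 1
        trial0 += cfg.n_trials_per_session
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_behavior(events: pd.DataFrame) -> dict[str, float]:
    """Per-subject behavioral summary.

    ``percent_correct`` follows the asymmetric-block convention: the share of
    20/80 and 80/20 trials on which the 0.8-probability action was chosen,
    in percent; 50/50 trials carry no notion of a better option and are
    excluded. ``percent_rewarded`` scores every trial by feedback instead.
    ``n_criterion_blocks`` counts blocks ended by reaching the learning
    criterion (the number of reversal stages the subject mastered).
    """
    asym = events[events["block_type"] != "50/50"]
    better = asym["block_type"].map(
        {"20/80": ACTION_RIGHT, "80/20": ACTION_LEFT}
    )
    correct = (asym["action"] == better).mean() if len(asym) else np.nan
    return {
        "percent_correct": 100.0 * float(correct),
        "percent_rewarded": 100.0 * float((events["outcome"] == REWARD).mean()),
        "n_criterion_blocks": int(events["reached_criterion"].sum()),
        "n_blocks": int(events["block_id"].nunique()),
        "n_trials": int(len(events)),
    }


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write the events TSV dialect (actions L/R, outcomes +1/-1)."""
    out = events[EVENT_COLUMNS[:7]].copy()
    out["action"] = out["action"].map(ACTION_CODES)
    out["onset_s"] = out["onset_s"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV; trials with a missing/invalid action (missed
    responses) are dropped, since the choice likelihood is defined only over
    made responses."""
    df = pd.read_csv(path, sep="\t")
    valid = df["action"].isin(ACTION_FROM_CODE)
    n_dropped = int((~valid).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} missed/invalid trials from {path}")
    df = df[valid].copy()
    df["action"] = df["action"].map(ACTION_FROM_CODE).astype(int)
    df["outcome"] = df["outcome"].astype(int)
    if "reached_criterion" not in df.columns:
        df["reached_criterion"] = False
    return df.reset_index(drop=True)
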
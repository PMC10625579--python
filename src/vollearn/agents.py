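"""Valenced Rescorla-Wagner agents for the volatility task.

The agent tracks, for shape A only, the estimated probability that shape A
carries the win (``v_win_A``) and the loss (``v_loss_A``); the schedule
guarantees shape B's probabilities are the complements.  Both estimates are
updated on every trial with a delta rule, because the task shows the
outcomes for both shapes regardless of choice (full feedback).  Choices are
generated by a softmax (logistic, for two options) over the net value
difference between the shapes, with a single inverse temperature across the
task and an optional constant bias toward shape A.

Model variants differ only in how learning rates are shared: a single
learning rate, one per outcome valence, or one per valence per block.
Value estimates restart at 0.5 at each block boundary because the stimuli
change between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit

from .schedule import TaskSchedule, generate_schedule, ScheduleConfig

__all__ = [
    "ModelSpec",
    "AgentParams",
    "SubjectDataset",
    "MODEL_FAMILY",
    "WINNING_MODEL",
    "update_value",
    "choice_probability",
    "value_trajectories",
    "simulate_agent",
    "log_likelihood",
]

START_MONEY = 1.50
WIN_PENCE = 0.15  # money added per win received, removed per loss received
P_FLOOR = 1e-10

N_BLOCKS = 3
VALENCES = ("win", "loss")


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters a model variant exposes.

    ``split_valence`` gives wins and losses separate learning rates;
    ``split_block`` gives every block its own learning rate(s);
    ``include_bias`` adds a constant additive preference for shape A.
    All variants share a single inverse temperature.
    """

    split_valence: bool = True
    split_block: bool = True
    include_bias: bool = False
    beta_policy: Literal["single"] = "single"

    @property
    def n_alpha(self) -> int:
        return (N_BLOCKS if self.split_block else 1) * (2 if self.split_valence else 1)

    @property
    def n_free(self) -> int:
        return self.n_alpha + 1 + int(self.include_bias)

    @property
    def name(self) -> str:
        parts = []
        if self.split_block and self.split_valence:
            parts.append("alpha_block_valence")
        elif self.split_valence:
            parts.append("alpha_valence")
        elif self.split_block:
            parts.append("alpha_block")
        else:
            parts.append("alpha_single")
        if self.include_bias:
            parts.append("bias")
        return "+".join(parts)


#: the model selected by the published comparison: learning rate per
#: block x valence, single inverse temperature, no bias
WINNING_MODEL = ModelSpec(split_valence=True, split_block=True, include_bias=False)

#: candidate family: each learning-rate sharing scheme with and without bias
MODEL_FAMILY: tuple[ModelSpec, ...] = tuple(
    ModelSpec(split_valence=sv, split_block=sb, include_bias=bias)
    for (sv, sb) in ((False, False), (True, False), (True, True))
    for bias in (False, True)
)


@dataclass
class AgentParams:
    """Agent parameters on their natural scales.

    ``alpha`` is always stored as a full (3 blocks x 2 valences) grid;
    shared learning rates are duplicated across the collapsed cells.
    Valence order is (win, loss).
    """

    alpha: np.ndarray  # (3, 2)
    beta: float
    bias: float = 0.0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (N_BLOCKS, 2):
            raise ValueError("alpha must have shape (3, 2)")
        if np.any((self.alpha < 0) | (self.alpha > 1)):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("inverse temperature must be >= 0")

    @classmethod
    def from_free(cls, spec: ModelSpec, alphas: Iterable[float], beta: float, bias: float = 0.0) -> "AgentParams":
        """Expand a model's free learning rates to the full (3, 2) grid."""
        a = np.asarray(list(alphas), dtype=float)
        if a.size != spec.n_alpha:
            raise ValueError(f"{spec.name} expects {spec.n_alpha} learning rates, got {a.size}")
        if spec.split_block and spec.split_valence:
            grid = a.reshape(N_BLOCKS, 2)
        elif spec.split_valence:
            grid = np.tile(a.reshape(1, 2), (N_BLOCKS, 1))
        elif spec.split_block:
            grid = np.tile(a.reshape(N_BLOCKS, 1), (1, 2))
        else:
            grid = np.full((N_BLOCKS, 2), a[0])
        return cls(alpha=grid, beta=float(beta), bias=float(bias) if spec.include_bias else 0.0)

    def free_alphas(self, spec: ModelSpec) -> np.ndarray:
        """Collapse the grid back to the model's free learning rates."""
        if spec.split_block and spec.split_valence:
            return self.alpha.ravel().copy()
        if spec.split_valence:
            return self.alpha[0].copy()
        if spec.split_block:
            return self.alpha[:, 0].copy()
        return np.array([self.alpha[0, 0]])


@dataclass
class SubjectDataset:
    """A subject's schedule, choices and money trajectory.

    ``choices`` has one row per trial with columns trial, block, chose_A,
    win_received, loss_received, money_after.
    """

    subject_id: str
    group: str
    order: str
    schedule: TaskSchedule
    choices: pd.DataFrame = field(repr=False)
    true_params: AgentParams | None = None

    @property
    def final_money(self) -> float:
        return float(self.choices["money_after"].iloc[-1])


def update_value(v: float, outcome: float, alpha: float) -> float:
    """Delta-rule update of a probability estimate: v + alpha * (o - v)."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    return v + alpha * (outcome - v)


def choice_probability(v_win_A, v_loss_A, beta: float, bias: float = 0.0):
    """Probability of choosing shape A.

    The net value of A relative to B is ``2 * (v_win_A - v_loss_A)`` (the
    complement structure doubles the difference), passed through a
    logistic with inverse temperature ``beta`` plus the additive bias.
    """
    return expit(2.0 * beta * (np.asarray(v_win_A) - np.asarray(v_loss_A)) + bias)


def _block_values(outcomes: np.ndarray, alpha: float, v0: float = 0.5) -> np.ndarray:
    """Pre-choice value estimates over one block given its outcome sequence.

    v[0] = v0; v[t] incorporates outcomes 0..t-1 via the delta rule.
    Implemented as a first-order linear filter for speed.
    """
    o = np.asarray(outcomes, dtype=float)
    if alpha == 0:
        return np.full(o.size, v0)
    post = lfilter([alpha], [1.0, -(1.0 - alpha)], o, zi=[(1.0 - alpha) * v0])[0]
    return np.concatenate(([v0], post[:-1]))


def value_trajectories(trials: pd.DataFrame, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pre-choice (v_win_A, v_loss_A) across all trials.

    Driven entirely by the scheduled outcome locations (full feedback), so
    the trajectory is independent of the subject's choices.  Values reset
    to 0.5 at each block start.
    """
    alpha = np.asarray(alpha, dtype=float)
    trials = trials.reset_index(drop=True)
    v_win = np.empty(len(trials))
    v_loss = np.empty(len(trials))
    for bi, sub in trials.groupby("block", sort=True):
        idx = sub.index.to_numpy()
        b = int(bi) - 1
        v_win[idx] = _block_values(sub["win_on_A"].to_numpy(), alpha[b, 0])
        v_loss[idx] = _block_values(sub["loss_on_A"].to_numpy(), alpha[b, 1])
    return v_win, v_loss


def choice_probabilities(trials: pd.DataFrame, params: AgentParams) -> np.ndarray:
    """Per-trial probability of choosing shape A under the agent."""
    v_win, v_loss = value_trajectories(trials, params.alpha)
    return choice_probability(v_win, v_loss, params.beta, params.bias)


def simulate_agent(
    schedule: TaskSchedule,
    params: AgentParams,
    rng: np.random.Generator,
    subject_id: str = "sim",
    group: str = "HC",
) -> SubjectDataset:
    """Simulate one subject's choices and money trajectory on a schedule.

    Because feedback is full, choice probabilities do not depend on earlier
    choices, so all 240 choices are drawn in one vectorised pass.
    """
    t = schedule.trials
    p_A = choice_probabilities(t, params)
    chose_A = rng.random(len(t)) < p_A
    win_received = chose_A == t["win_on_A"].to_numpy()
    loss_received = chose_A == t["loss_on_A"].to_numpy()
    money = START_MONEY + WIN_PENCE * np.cumsum(
        win_received.astype(int) - loss_received.astype(int)
    )
    choices = pd.DataFrame(
        {
            "trial": t["trial"].to_numpy(),
            "block": t["block"].to_numpy(),
            "chose_A": chose_A,
            "win_received": win_received,
            "loss_received": loss_received,
            "money_after": np.round(money, 10),
        }
    )
    return SubjectDataset(
        subject_id=subject_id,
        group=group,
        order=schedule.config.block_order,
        schedule=schedule,
        choices=choices,
        true_params=params,
    )


def log_likelihood(dataset: SubjectDataset, params: AgentParams) -> float:
    """Log probability of the subject's observed choices under the agent.

    The latent value trajectory is recomputed from the schedule's realised
    outcomes, never from the subject's choices.  Per-trial probabilities
    are floored at 1e-10 to keep the result finite.
    """
    p_A = choice_probabilities(dataset.schedule.trials, params)
    chose_A = dataset.choices["chose_A"].to_numpy()
    p = np.where(chose_A, p_A, 1.0 - p_A)
    return float(np.sum(np.log(np.maximum(p, P_FLOOR))))
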
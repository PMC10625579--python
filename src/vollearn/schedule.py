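"""Generation and validation of the three-block volatility task.

The task presents two abstract shapes on every trial.  Win and loss
outcomes are assigned to the shapes independently of each other, and the
probability that shape A carries an outcome is either *volatile*
(alternating between a high and a low level every 14-30 trials) or
*stable* (fixed at 0.5).  Block 1 has both outcome valences volatile;
in blocks 2 and 3 exactly one valence is volatile, in a counterbalanced
order.  Shape B's probabilities are the complement of shape A's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleConfig",
    "BlockSpec",
    "TaskSchedule",
    "build_probability_trajectory",
    "generate_schedule",
    "realize_outcomes",
    "validate_schedule",
    "schedule_to_frame",
    "schedule_from_frame",
]

BlockOrder = Literal["win_volatile_second", "loss_volatile_second"]
Volatility = Literal["volatile", "stable"]

#: levels a scheduled probability may take
P_LEVELS = (0.15, 0.5, 0.85)


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of the task schedule.

    Defaults reproduce the published design: probabilities alternate
    between 0.85 and 0.15 when volatile (0.5 when stable), contingency
    epochs last 14-30 trials, and each of the three blocks has 80 trials.
    """

    p_high: float = 0.85
    p_low: float = 0.15
    p_stable: float = 0.5
    epoch_min: int = 14
    epoch_max: int = 30
    n_trials_per_block: int = 80
    block_order: BlockOrder = "win_volatile_second"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_low < self.p_stable < self.p_high < 1):
            raise ValueError("require 0 < p_low < p_stable < p_high < 1")
        if abs(self.p_low - (1 - self.p_high)) > 1e-12:
            raise ValueError("p_low must equal 1 - p_high")
        if not (1 <= self.epoch_min <= self.epoch_max <= self.n_trials_per_block):
            raise ValueError("require 1 <= epoch_min <= epoch_max <= n_trials_per_block")
        if self.block_order not in ("win_volatile_second", "loss_volatile_second"):
            raise ValueError(f"unknown block_order {self.block_order!r}")


@dataclass(frozen=True)
class BlockSpec:
    index: int  # 1..3
    win_condition: Volatility
    loss_condition: Volatility


@dataclass
class TaskSchedule:
    """A realised 240-trial schedule.

    ``trials`` is a DataFrame with one row per trial and columns
    trial (1-based, contiguous), block, win_condition, loss_condition,
    p_win_A, p_loss_A, win_on_A, loss_on_A, win_shown_first,
    inter_outcome_delay_s.
    """

    config: ScheduleConfig
    blocks: list[BlockSpec]
    trials: pd.DataFrame = field(repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def block_specs(order: BlockOrder) -> list[BlockSpec]:
    """Block conditions: block 1 doubly volatile, blocks 2/3 per order."""
    if order == "win_volatile_second":
        return [
            BlockSpec(1, "volatile", "volatile"),
            BlockSpec(2, "volatile", "stable"),
            BlockSpec(3, "stable", "volatile"),
        ]
    return [
        BlockSpec(1, "volatile", "volatile"),
        BlockSpec(2, "stable", "volatile"),
        BlockSpec(3, "volatile", "stable"),
    ]


def _sample_epoch_lengths(n_trials: int, cfg: ScheduleConfig, rng: np.random.Generator) -> list[int]:
    """One draw of the budget rule: sample epoch lengths uniformly until the
    remainder is below ``epoch_min``, absorbing the remainder into the last
    epoch.  May return an illegal partition; the caller rejects those."""
    lengths: list[int] = []
    remaining = n_trials
    while remaining >= cfg.epoch_min:
        draw = int(rng.integers(cfg.epoch_min, cfg.epoch_max + 1))
        if remaining - draw < cfg.epoch_min:
            draw = remaining  # extend/trim the final epoch to fill the block
        lengths.append(draw)
        remaining -= draw
    return lengths


def build_probability_trajectory(
    condition: Volatility,
    n_trials: int,
    config: ScheduleConfig,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Per-trial scheduled probability for one valence within one block.

    Stable condition: constant ``p_stable``.  Volatile: alternating epochs
    of ``p_high``/``p_low`` with every epoch length in
    ``[epoch_min, epoch_max]`` and, to keep the block mean at exactly 0.5,
    an equal number of trials at each level.  The starting level is chosen
    at random.  Partitions are drawn by rejection sampling; with the
    default geometry (80 trials, epochs of 14-30) balanced partitions
    always have four strictly alternating epochs.
    """
    if condition == "stable":
        return np.full(n_trials, config.p_stable)
    if condition != "volatile":
        raise ValueError(f"unknown condition {condition!r}")
    if n_trials % 2:
        raise ValueError("volatile trajectory needs an even trial count for exact balance")

    target = n_trials // 2
    for _ in range(max_attempts):
        lengths = _sample_epoch_lengths(n_trials, config, rng)
        if any(not (config.epoch_min <= L <= config.epoch_max) for L in lengths):
            continue
        start_high = bool(rng.integers(2))
        # trials at the starting level under strict alternation
        start_total = sum(lengths[0::2])
        if start_total != target:
            continue
        levels = np.empty(len(lengths))
        levels[0::2] = config.p_high if start_high else config.p_low
        levels[1::2] = config.p_low if start_high else config.p_high
        return np.repeat(levels, lengths)
    raise ValueError(
        "could not partition the block into balanced epochs; "
        f"no legal alternating partition of {n_trials} trials with epochs in "
        f"[{config.epoch_min}, {config.epoch_max}] was found in {max_attempts} draws"
    )


def realize_outcomes(
    p_win_A: np.ndarray, p_loss_A: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli draws of which shape carries each outcome.

    Win and loss placements are independent across valences and trials;
    exactly one shape carries each outcome on every trial (shape B carries
    it whenever shape A does not).
    """
    p_win_A = np.asarray(p_win_A, dtype=float)
    p_loss_A = np.asarray(p_loss_A, dtype=float)
    win_on_A = rng.random(p_win_A.shape) < p_win_A
    loss_on_A = rng.random(p_loss_A.shape) < p_loss_A
    return win_on_A, loss_on_A


def generate_schedule(config: ScheduleConfig | None = None) -> TaskSchedule:
    """Generate a full 3 x 80-trial schedule from a config.

    Within each block the win-before-loss display order alternates
    deterministically (exact counterbalance) and the delay between the two
    outcome displays is uniform on [2, 6] s.
    """
    config = config or ScheduleConfig()
    rng = np.random.default_rng(config.seed)
    blocks = block_specs(config.block_order)
    n = config.n_trials_per_block

    rows = []
    for spec in blocks:
        p_win = build_probability_trajectory(spec.win_condition, n, config, rng)
        p_loss = build_probability_trajectory(spec.loss_condition, n, config, rng)
        win_on_A, loss_on_A = realize_outcomes(p_win, p_loss, rng)
        delays = rng.uniform(2.0, 6.0, size=n)
        win_first = (np.arange(n) % 2) == 0
        rows.append(
            pd.DataFrame(
                {
                    "trial": np.arange(n) + 1 + (spec.index - 1) * n,
                    "block": spec.index,
                    "win_condition": spec.win_condition,
                    "loss_condition": spec.loss_condition,
                    "p_win_A": p_win,
                    "p_loss_A": p_loss,
                    "win_on_A": win_on_A,
                    "loss_on_A": loss_on_A,
                    "win_shown_first": win_first,
                    "inter_outcome_delay_s": delays,
                }
            )
        )
    trials = pd.concat(rows, ignore_index=True)
    return TaskSchedule(config=config, blocks=blocks, trials=trials)


def _check_runs(p: np.ndarray, cfg: ScheduleConfig, label: str, violations: list[str]) -> None:
    change = np.flatnonzero(np.diff(p) != 0)
    bounds = np.concatenate(([0], change + 1, [len(p)]))
    run_lengths = np.diff(bounds)
    for L in run_lengths:
        if not (cfg.epoch_min <= L <= cfg.epoch_max):
            violations.append(
                f"{label}: epoch length {L} outside [{cfg.epoch_min}, {cfg.epoch_max}]"
            )


def validate_schedule(schedule: TaskSchedule) -> list[str]:
    """Check every schedule invariant; returns a list of violation messages
    (empty when the schedule is valid)."""
    cfg = schedule.config
    t = schedule.trials
    violations: list[str] = []
    n = cfg.n_trials_per_block

    if len(t) != 3 * n:
        violations.append(f"expected {3 * n} trials, found {len(t)}")
    if not np.array_equal(t["trial"].to_numpy(), np.arange(len(t)) + 1):
        violations.append("trial numbers are not 1-based contiguous")

    legal = set(P_LEVELS)
    for col in ("p_win_A", "p_loss_A"):
        bad = set(np.round(t[col].unique(), 12)) - legal
        if bad:
            violations.append(f"{col}: illegal probability level(s) {sorted(bad)}")

    spec_by_block = {b.index: b for b in schedule.blocks}
    b1 = spec_by_block.get(1)
    if b1 and not (b1.win_condition == b1.loss_condition == "volatile"):
        violations.append("block 1 must have both valences volatile")
    if 2 in spec_by_block and 3 in spec_by_block:
        b2, b3 = spec_by_block[2], spec_by_block[3]
        for b in (b2, b3):
            if (b.win_condition == "volatile") == (b.loss_condition == "volatile"):
                violations.append(f"block {b.index} must have exactly one volatile valence")
        if b2.win_condition == b3.win_condition:
            violations.append("blocks 2 and 3 must differ in which valence is volatile")

    for bi, sub in t.groupby("block"):
        spec = spec_by_block.get(int(bi))
        if spec is None:
            violations.append(f"block {bi} missing from block specs")
            continue
        for valence, cond, col in (
            ("win", spec.win_condition, "p_win_A"),
            ("loss", spec.loss_condition, "p_loss_A"),
        ):
            p = sub[col].to_numpy()
            label = f"block {bi} {valence}"
            if cond == "stable":
                if not np.allclose(p, cfg.p_stable):
                    violations.append(f"{label}: stable probabilities not constant {cfg.p_stable}")
            else:
                if not np.all(np.isin(np.round(p, 12), [cfg.p_low, cfg.p_high])):
                    violations.append(f"{label}: illegal probability level in volatile trajectory")
                _check_runs(p, cfg, label, violations)
            if abs(p.mean() - 0.5) > 1e-9:
                violations.append(f"{label}: mean scheduled probability {p.mean():.4f} != 0.5")

    delays = t["inter_outcome_delay_s"].to_numpy()
    if np.any((delays < 2.0) | (delays > 6.0)):
        violations.append("inter-outcome delays outside [2, 6] s")
    return violations


SCHEDULE_COLUMNS = [
    "trial",
    "block",
    "win_condition",
    "loss_condition",
    "p_win_A",
    "p_loss_A",
    "win_on_A",
    "loss_on_A",
    "win_shown_first",
    "inter_outcome_delay_s",
]


def schedule_to_frame(schedule: TaskSchedule) -> pd.DataFrame:
    return schedule.trials[SCHEDULE_COLUMNS].copy()


def schedule_from_frame(frame: pd.DataFrame, config: ScheduleConfig | None = None) -> TaskSchedule:
    """Rebuild a TaskSchedule from its tabular form."""
    frame = frame.copy()
    for col in ("win_on_A", "loss_on_A", "win_shown_first"):
        frame[col] = frame[col].astype(bool)
    blocks = []
    for bi, sub in frame.groupby("block"):
        blocks.append(
            BlockSpec(int(bi), str(sub["win_condition"].iloc[0]), str(sub["loss_condition"].iloc[0]))
        )
    cfg = config or ScheduleConfig(
        n_trials_per_block=int(frame.groupby("block").size().iloc[0])
    )
    win_vol_block = next((b.index for b in blocks if b.index > 1 and b.win_condition == "volatile"), 2)
    cfg = replace(cfg, block_order="win_volatile_second" if win_vol_block == 2 else "loss_volatile_second")
    return TaskSchedule(config=cfg, blocks=sorted(blocks, key=lambda b: b.index), trials=frame.reset_index(drop=True))
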
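import numpy as np
import pandas as pd
import pytest

from vollearn.agents import AgentParams, WINNING_MODEL, simulate_agent
from vollearn.schedule import ScheduleConfig, TaskSchedule, BlockSpec, generate_schedule


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(ScheduleConfig(seed=11))


@pytest.fixture(scope="session")
def agent_params():
    # distinct volatile (block 1 + valence-volatile block) vs stable rates
    return AgentParams.from_free(WINNING_MODEL, [0.4, 0.35, 0.4, 0.18, 0.18, 0.35], beta=6.0)


@pytest.fixture(scope="session")
def dataset(schedule, agent_params):
    return simulate_agent(schedule, agent_params, np.random.default_rng(5), subject_id="s1")


def toy_schedule(p_win_A, p_loss_A, win_on_A, loss_on_A, block=None, win_condition="volatile", loss_condition="stable"):
    """Hand-built schedule for toy tests (single block by default)."""
    n = len(win_on_A)
    block = block if block is not None else np.ones(n, dtype=int)
    trials = pd.DataFrame(
        {
            "trial": np.arange(n) + 1,
            "block": block,
            "win_condition": win_condition,
            "loss_condition": loss_condition,
            "p_win_A": p_win_A,
            "p_loss_A": p_loss_A,
            "win_on_A": np.asarray(win_on_A, dtype=bool),
            "loss_on_A": np.asarray(loss_on_A, dtype=bool),
            "win_shown_first": True,
            "inter_outcome_delay_s": 4.0,
        }
    )
    blocks = [BlockSpec(int(b), win_condition, loss_condition) for b in sorted(set(block))]
    n_block = int((np.asarray(block) == block[0]).sum())
    cfg = ScheduleConfig(n_trials_per_block=n_block, epoch_min=1, epoch_max=n_block)
    return TaskSchedule(config=cfg, blocks=blocks, trials=trials)
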
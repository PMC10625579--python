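"""Generate one volatility-task schedule and inspect its structure.

Three 80-trial blocks: block 1 has both win and loss probabilities
volatile (alternating 0.85/0.15 every 14-30 trials), blocks 2 and 3 hold
one valence stable at 0.5 while the other stays volatile.
"""

import numpy as np

from vollearn import ScheduleConfig, generate_schedule, validate_schedule

schedule = generate_schedule(ScheduleConfig(seed=7, block_order="win_volatile_second"))
trials = schedule.trials

print("violations:", validate_schedule(schedule) or "none")
for block, sub in trials.groupby("block"):
    p = sub["p_win_A"].to_numpy()
    runs = np.diff(np.concatenate(([0], np.flatnonzero(np.diff(p) != 0) + 1, [len(p)])))
    print(
        f"block {block}: win {sub.win_condition.iloc[0]:>8}, loss {sub.loss_condition.iloc[0]:>8}; "
        f"win-probability levels {sorted(set(p))}, epochs {runs.tolist()}, mean {p.mean():.2f}"
    )
# Every volatile trajectory averages exactly 0.5 within a block, so the
# schedule never favours one shape; epoch lengths always lie in [14, 30].
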
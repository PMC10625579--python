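"""Synthetic study cohorts: group-labelled choice and pupil data.

The generator emulates the study conditions the analyses assume: three
groups of subjects (RA, recovered from anorexia nervosa, n = 25; EA,
elevated eating-disorder symptoms, n = 25; HC, healthy controls, n = 32)
performing the 3 x 80-trial volatility task with counterbalanced block
order.  Each subject is a valenced Rescorla-Wagner agent whose
volatile-minus-stable learning-rate difference ("adjustment") is drawn
per valence from the group's normal distribution — by default the
published group means and SDs (RA 0.191/0.169, EA 0.134/0.180, HC
0.107/0.195).  Stable learning rates are logit-normal around 0.2, the
inverse temperature log-normal with median 6 (a calibration that keeps
simulated stay probabilities in the descriptive range of human play, not
a published fact), and block-1 learning rates equal the valence's
volatile rate (block 1 is volatile for both valences).

Pupil traces are generated as a baseline plus a gamma-shaped impulse
response to every outcome display (mode ~1 s after onset), scaled per
condition and group, plus white noise, slow drift and Poisson blinks.
Group-dependent receipt effects express the published pattern (the RA
preset elevates dilation to stable wins and suppresses it to stable
losses), and the RA preset couples each subject's volatile-win response
to their reward learning-rate adjustment so that the within-RA
pupil-behaviour correlation is positive by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist

from .agents import AgentParams, SubjectDataset, simulate_agent
from .pupil import PupilTrace
from .schedule import ScheduleConfig, generate_schedule

__all__ = [
    "GroupPreset",
    "PupilSimConfig",
    "CohortConfig",
    "CohortData",
    "DEFAULT_PRESETS",
    "sample_group_params",
    "conditions_to_agent_params",
    "simulate_pupil_trace",
    "simulate_cohort",
]

VALENCES = ("win", "loss")


@dataclass(frozen=True)
class GroupPreset:
    """Generative settings for one participant group.

    ``adjustment_mean``/``adjustment_sd`` parametrise the per-valence
    normal distribution of volatile-minus-stable learning-rate
    differences.  ``receipt_effect`` maps (valence, volatility) to the
    extra pupil dilation (arbitrary units) when the chosen shape carries
    the outcome.  ``coupling_slope`` adds, for the (win, volatile) cell,
    a per-subject component proportional to the subject's standardised
    reward adjustment (``coupling_noise_sd`` is the uncoupled
    between-subject spread of that cell).
    """

    name: str
    n_subjects: int
    adjustment_mean: float
    adjustment_sd: float
    stable_alpha_logit_mean: float = float(logit(0.2))
    stable_alpha_logit_sd: float = 0.4
    beta_log_mean: float = float(np.log(6.0))
    beta_log_sd: float = 0.4
    alpha_clip: tuple[float, float] = (0.02, 0.98)
    receipt_effect: dict = field(
        default_factory=lambda: {
            ("win", "volatile"): 0.30,
            ("win", "stable"): 0.15,
            ("loss", "volatile"): 0.30,
            ("loss", "stable"): 0.15,
        }
    )
    coupling_slope: float = 0.0
    coupling_noise_sd: float = 0.10


DEFAULT_PRESETS: tuple[GroupPreset, ...] = (
    GroupPreset(
        name="RA",
        n_subjects=25,
        adjustment_mean=0.191,
        adjustment_sd=0.169,
        receipt_effect={
            ("win", "volatile"): 0.30,
            ("win", "stable"): 0.35,
            ("loss", "volatile"): 0.30,
            ("loss", "stable"): 0.05,
        },
        coupling_slope=0.12,
    ),
    GroupPreset(name="EA", n_subjects=25, adjustment_mean=0.134, adjustment_sd=0.180),
    GroupPreset(name="HC", n_subjects=32, adjustment_mean=0.107, adjustment_sd=0.195),
)


@dataclass(frozen=True)
class PupilSimConfig:
    """Noise and response-kernel model for simulated pupil streams."""

    sampling_rate: float = 50.0
    baseline: float = 5.0
    base_response: float = 0.2  # dilation to any outcome display, a.u.
    kernel_shape: float = 3.0
    kernel_scale_s: float = 0.5  # mode at (shape - 1) * scale = 1 s
    kernel_duration_s: float = 5.0
    white_sd: float = 0.05
    drift_sd: float = 0.1
    drift_timescale_s: float = 30.0
    blink_rate_hz: float = 0.05
    blink_ms: tuple[float, float] = (100.0, 400.0)
    outcome_display_s: float = 1.0  # first outcome appears 1 s after trial start
    post_trial_s: float = 7.0  # quiet period after the second outcome


@dataclass(frozen=True)
class CohortConfig:
    presets: tuple[GroupPreset, ...] = DEFAULT_PRESETS
    master_seed: int = 0
    schedule_policy: str = "per_subject"  # or "shared": one schedule per order
    simulate_pupil: bool = True
    pupil: PupilSimConfig = PupilSimConfig()
    schedule: ScheduleConfig = ScheduleConfig()


@dataclass
class CohortData:
    datasets: list[SubjectDataset]
    traces: list[PupilTrace]
    manifest: pd.DataFrame  # true generative parameters per subject


def sample_group_params(preset: GroupPreset, rng: np.random.Generator) -> list[dict]:
    """Draw per-subject condition-level agent parameters for one group.

    Each subject gets, per valence, a stable learning rate (logit-normal)
    and an adjustment (normal); the volatile rate is their clipped sum,
    and block 1 uses the volatile rate.  Warns if clipping shifts the
    realised mean adjustment by more than 0.05.
    """
    out = []
    for _ in range(preset.n_subjects):
        a_stable = expit(rng.normal(preset.stable_alpha_logit_mean, preset.stable_alpha_logit_sd, 2))
        adj = rng.normal(preset.adjustment_mean, preset.adjustment_sd, 2)
        a_vol = np.clip(a_stable + adj, *preset.alpha_clip)
        a_stable = np.clip(a_stable, *preset.alpha_clip)
        out.append(
            {
                "alpha_stable": a_stable,
                "alpha_volatile": a_vol,
                "adjustment_drawn": adj,
                "adjustment": a_vol - a_stable,
                "beta": float(np.exp(rng.normal(preset.beta_log_mean, preset.beta_log_sd))),
                "bias": 0.0,
            }
        )
    drawn = np.mean([s["adjustment_drawn"] for s in out])
    realised = np.mean([s["adjustment"] for s in out])
    if abs(drawn - realised) > 0.05:
        warnings.warn(
            f"{preset.name}: clipping moved the mean adjustment by {abs(drawn - realised):.3f}",
            RuntimeWarning,
        )
    return out


def conditions_to_agent_params(cond: dict, order: str) -> AgentParams:
    """Assemble the (block, valence) learning-rate grid for a block order.

    Block 1 is volatile for both valences; the valence-volatile block
    takes the volatile rate and the other block the stable rate.
    """
    a_s, a_v = cond["alpha_stable"], cond["alpha_volatile"]
    grid = np.empty((3, 2))
    grid[0] = a_v
    if order == "win_volatile_second":
        grid[1] = (a_v[0], a_s[1])
        grid[2] = (a_s[0], a_v[1])
    elif order == "loss_volatile_second":
        grid[1] = (a_s[0], a_v[1])
        grid[2] = (a_v[0], a_s[1])
    else:
        raise ValueError(f"unknown block order {order!r}")
    return AgentParams(alpha=grid, beta=cond["beta"], bias=cond["bias"])


def _gamma_kernel(cfg: PupilSimConfig) -> np.ndarray:
    """Unit-peak gamma impulse response sampled at the working rate."""
    t = np.arange(0, cfg.kernel_duration_s, 1.0 / cfg.sampling_rate)
    g = gamma_dist.pdf(t, a=cfg.kernel_shape, scale=cfg.kernel_scale_s)
    return g / g.max()


def build_outcome_events(dataset: SubjectDataset, cfg: PupilSimConfig) -> pd.DataFrame:
    """Outcome-display onset times for every trial.

    The first outcome appears ``outcome_display_s`` after trial start,
    the second after the trial's jittered inter-outcome delay; the next
    trial starts ``post_trial_s`` later.  Returns one row per outcome
    event (two per trial) with onset_ms, valence, received, volatility.
    """
    t = dataset.schedule.trials
    c = dataset.choices
    spec_by_block = {b.index: b for b in dataset.schedule.blocks}
    rows = []
    clock = 1.0  # settle-in second before the first trial
    for sched, ch in zip(t.itertuples(index=False), c.itertuples(index=False)):
        first_on = clock + cfg.outcome_display_s
        second_on = first_on + sched.inter_outcome_delay_s
        order = ("win", "loss") if sched.win_shown_first else ("loss", "win")
        onsets = {order[0]: first_on, order[1]: second_on}
        spec = spec_by_block[int(sched.block)]
        for valence in ("win", "loss"):
            rows.append(
                {
                    "trial": int(sched.trial),
                    "block": int(sched.block),
                    "valence": valence,
                    "received": bool(ch.win_received if valence == "win" else ch.loss_received),
                    "volatility": spec.win_condition if valence == "win" else spec.loss_condition,
                    "onset_ms": onsets[valence] * 1000.0,
                }
            )
        clock = second_on + cfg.post_trial_s
    return pd.DataFrame(rows)


def simulate_pupil_trace(
    dataset: SubjectDataset,
    preset: GroupPreset,
    cfg: PupilSimConfig,
    rng: np.random.Generator,
    reward_adjustment_z: float = 0.0,
) -> PupilTrace:
    """Simulate one subject's pupil stream aligned to their outcomes.

    ``reward_adjustment_z`` is the subject's standardised reward
    learning-rate adjustment, used by presets with a nonzero coupling
    slope to tie the (win, volatile) receipt response to behaviour.
    """
    events = build_outcome_events(dataset, cfg)
    rate = cfg.sampling_rate
    duration_s = events["onset_ms"].max() / 1000.0 + cfg.post_trial_s + 1.0
    n = int(np.ceil(duration_s * rate))
    t_ms = np.arange(n) * (1000.0 / rate)

    # per-subject receipt effects: preset values, with the volatile-win
    # cell coupled to behaviour and jittered between subjects
    effects = dict(preset.receipt_effect)
    effects[("win", "volatile")] = (
        effects[("win", "volatile")]
        + preset.coupling_slope * reward_adjustment_z
        + rng.normal(0.0, preset.coupling_noise_sd)
    )

    impulses = np.zeros(n)
    for ev in events.itertuples(index=False):
        idx = int(round(ev.onset_ms / 1000.0 * rate))
        amp = cfg.base_response
        if ev.received:
            amp += effects[(ev.valence, ev.volatility)]
        impulses[idx] += amp
    kernel = _gamma_kernel(cfg)
    response = np.convolve(impulses, kernel)[:n]

    drift = np.zeros(n)
    if cfg.drift_sd > 0:
        n_knots = max(int(duration_s / cfg.drift_timescale_s) + 2, 2)
        knot_t = np.linspace(0, n - 1, n_knots)
        drift = np.interp(np.arange(n), knot_t, rng.normal(0.0, cfg.drift_sd, n_knots))

    pupil = cfg.baseline + response + drift + rng.normal(0.0, cfg.white_sd, n)
    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(cfg.blink_rate_hz * duration_s)
    for _ in range(n_blinks):
        start = int(rng.integers(0, n))
        width = int(round(rng.uniform(*cfg.blink_ms) / 1000.0 * rate))
        pupil[start : start + width] = 0.0
        valid[start : start + width] = False

    return PupilTrace(
        subject_id=dataset.subject_id,
        t_ms=t_ms,
        pupil=pupil,
        valid=valid,
        sampling_rate=rate,
        events=events,
    )


def simulate_cohort(config: CohortConfig = CohortConfig()) -> CohortData:
    """Simulate a full cohort: schedules, choices and (optionally) pupil
    streams, reproducible end-to-end from the master seed.

    Block order alternates within each group (counterbalanced to within
    one subject); schedules are regenerated per subject unless
    ``schedule_policy`` is "shared" (one schedule per block order).
    """
    ss = np.random.SeedSequence(config.master_seed)
    datasets: list[SubjectDataset] = []
    traces: list[PupilTrace] = []
    manifest_rows = []

    shared = {}
    if config.schedule_policy == "shared":
        for i, order in enumerate(("win_volatile_second", "loss_volatile_second")):
            seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31))
            shared[order] = generate_schedule(replace(config.schedule, block_order=order, seed=seed))

    for preset in config.presets:
        group_ss = ss.spawn(1)[0]
        rng = np.random.default_rng(group_ss)
        conds = sample_group_params(preset, rng)
        adj_win = np.array([c["adjustment"][0] for c in conds])
        z_win = (adj_win - adj_win.mean()) / adj_win.std() if adj_win.std() > 0 else np.zeros_like(adj_win)
        for i, cond in enumerate(conds):
            order = "win_volatile_second" if i % 2 == 0 else "loss_volatile_second"
            sid = f"{preset.name}{i + 1:03d}"
            if config.schedule_policy == "shared":
                sched = shared[order]
            else:
                sched = generate_schedule(
                    replace(config.schedule, block_order=order, seed=int(rng.integers(2**31)))
                )
            params = conditions_to_agent_params(cond, order)
            ds = simulate_agent(sched, params, rng, subject_id=sid, group=preset.name)
            datasets.append(ds)
            if config.simulate_pupil:
                traces.append(
                    simulate_pupil_trace(ds, preset, config.pupil, rng, reward_adjustment_z=float(z_win[i]))
                )
            manifest_rows.append(
                {
                    "subject_id": sid,
                    "group": preset.name,
                    "order": order,
                    "alpha_stable_win": cond["alpha_stable"][0],
                    "alpha_stable_loss": cond["alpha_stable"][1],
                    "alpha_volatile_win": cond["alpha_volatile"][0],
                    "alpha_volatile_loss": cond["alpha_volatile"][1],
                    "adjustment_win": cond["adjustment"][0],
                    "adjustment_loss": cond["adjustment"][1],
                    "beta": cond["beta"],
                    "bias": cond["bias"],
                }
            )
    return CohortData(datasets=datasets, traces=traces, manifest=pd.DataFrame(manifest_rows))
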
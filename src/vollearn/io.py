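"""Delimited-text I/O, run configuration and seed policy.

All tables are comma-separated UTF-8 with a header row and '.' decimals;
probabilities and currency are serialised at full double precision.
Every stochastic stage derives its generator deterministically from the
master seed and the stage name.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import AgentParams, SubjectDataset
from .cohort import CohortData, DEFAULT_PRESETS, GroupPreset
from .pupil import PupilTrace
from .schedule import SCHEDULE_COLUMNS, TaskSchedule, schedule_from_frame, schedule_to_frame

__all__ = [
    "stage_rng",
    "RunConfig",
    "load_config",
    "write_schedule",
    "read_schedule",
    "write_subject",
    "read_subject",
    "write_trace",
    "read_trace",
    "write_cohort",
    "read_cohort",
]

CHOICE_COLUMNS = ["chose_A", "win_received", "loss_received", "money_after"]


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator: master seed + hashed stage name."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())]))


def stage_seed(master_seed: int, stage: str) -> int:
    """A plain integer seed (< 2^31) derived from a stage name."""
    return int(stage_rng(master_seed, stage).integers(2**31))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    master_seed: int = 0
    outdir: str | None = None
    simulate_pupil: bool = True
    run_model_comparison: bool = False
    n_restarts: int = 3
    n_mc: int = 1000
    n_perm: int = 1000
    correlation_window_ms: tuple[float, float] = (342.0, 4904.0)
    group_sizes: dict = field(default_factory=dict)  # e.g. {"RA": 6} for quick runs
    log_level: str = "INFO"

    def presets(self) -> tuple[GroupPreset, ...]:
        out = []
        for p in DEFAULT_PRESETS:
            n = int(self.group_sizes.get(p.name, p.n_subjects))
            out.append(GroupPreset(**{**asdict_preset(p), "n_subjects": n}))
        return tuple(out)


def asdict_preset(p: GroupPreset) -> dict:
    d = asdict(p)
    d["receipt_effect"] = dict(p.receipt_effect)
    return d


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**known)
    if isinstance(cfg.correlation_window_ms, list):
        cfg.correlation_window_ms = tuple(cfg.correlation_window_ms)
    return cfg


# ---------------------------------------------------------------------------
# tables


def write_schedule(schedule: TaskSchedule, path: str | Path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def read_schedule(path: str | Path) -> TaskSchedule:
    return schedule_from_frame(pd.read_csv(path))


def write_subject(dataset: SubjectDataset, path: str | Path) -> None:
    """One combined trial log: schedule columns + choices + labels."""
    df = schedule_to_frame(dataset.schedule)
    for col in CHOICE_COLUMNS:
        df[col] = dataset.choices[col].to_numpy()
    df.insert(0, "subject_id", dataset.subject_id)
    df.insert(1, "group", dataset.group)
    df.insert(2, "order", dataset.order)
    df.to_csv(path, index=False)


def read_subject(path: str | Path) -> SubjectDataset:
    df = pd.read_csv(path)
    schedule = schedule_from_frame(df[SCHEDULE_COLUMNS])
    choices = df[["trial", "block"] + CHOICE_COLUMNS].copy()
    for col in ("chose_A", "win_received", "loss_received"):
        choices[col] = choices[col].astype(bool)
    return SubjectDataset(
        subject_id=str(df["subject_id"].iloc[0]),
        group=str(df["group"].iloc[0]),
        order=str(df["order"].iloc[0]),
        schedule=schedule,
        choices=choices.reset_index(drop=True),
    )


def write_trace(trace: PupilTrace, samples_path: str | Path, events_path: str | Path) -> None:
    pd.DataFrame({"t_ms": trace.t_ms, "pupil": trace.pupil, "valid": trace.valid.astype(int)}).to_csv(
        samples_path, index=False
    )
    trace.events.to_csv(events_path, index=False)


def read_trace(samples_path: str | Path, events_path: str | Path, subject_id: str, sampling_rate: float | None = None) -> PupilTrace:
    s = pd.read_csv(samples_path)
    events = pd.read_csv(events_path)
    t = s["t_ms"].to_numpy(dtype=float)
    if sampling_rate is None:
        sampling_rate = 1000.0 / float(np.median(np.diff(t)))
    return PupilTrace(
        subject_id=subject_id,
        t_ms=t,
        pupil=s["pupil"].to_numpy(dtype=float),
        valid=s["valid"].to_numpy().astype(bool),
        sampling_rate=sampling_rate,
        events=events,
    )


def write_cohort(cohort: CohortData, outdir: str | Path) -> None:
    """Write trial logs, pupil sample/event files and the manifest of true
    generative parameters (for recovery scoring)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(outdir / "manifest.csv", index=False)
    traces = {t.subject_id: t for t in cohort.traces}
    for ds in cohort.datasets:
        write_subject(ds, outdir / f"{ds.subject_id}_trials.csv")
        if ds.subject_id in traces:
            write_trace(
                traces[ds.subject_id],
                outdir / f"{ds.subject_id}_samples.csv",
                outdir / f"{ds.subject_id}_events.csv",
            )


def read_cohort(outdir: str | Path) -> CohortData:
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    datasets, traces = [], []
    for sid in manifest["subject_id"]:
        datasets.append(read_subject(outdir / f"{sid}_trials.csv"))
        sp, ep = outdir / f"{sid}_samples.csv", outdir / f"{sid}_events.csv"
        if sp.exists():
            traces.append(read_trace(sp, ep, subject_id=str(sid)))
    return CohortData(datasets=datasets, traces=traces, manifest=manifest)
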
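"""Pupillometry pipeline: preprocessing, epoching, condition contrasts,
cluster-based permutation inference and pupil-behaviour correlation.

The pipeline consumes a regularly sampled pupil-diameter stream with a
per-sample validity flag and an event table giving the onset of each
outcome display (one win and one loss event per trial, each tagged with
whether the chosen shape received that outcome and whether the valence
was volatile in that block).

Preprocessing marks invalid or zero samples as blinks, pads the blink
mask, linearly interpolates across it, optionally smooths, and resamples
to a common working rate (50 Hz by default).  Epochs span 1 s before to
6 s after each outcome onset, baseline-corrected by the mean of the
pre-onset second.  Epochs with more than half their samples interpolated
are excluded; subjects for whom more than half the task trials are that
badly interpolated are removed entirely.

For inference, each subject contributes one averaged series per valence:
the receipt-minus-non-receipt dilation under volatile outcomes minus the
same contrast under stable outcomes.  At each timepoint a split-plot
model with group (between) and valence (within, subject-paired) is
evaluated; contiguous runs of pointwise-significant timepoints form
clusters scored by summed F (cluster mass), and cluster p-values come
from the permutation distribution of the maximal cluster mass (group
labels shuffled across subjects, valence labels flipped within subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behaviour import fisher_compare

__all__ = [
    "PupilConfig",
    "PupilTrace",
    "ClusterResult",
    "ClusterTestReport",
    "preprocess_trace",
    "epoch_outcomes",
    "apply_exclusions",
    "condition_timeseries",
    "cluster_permutation_test",
    "window_permutation_test",
    "pupil_behaviour_correlation",
]


class UnprocessableSubjectError(RuntimeError):
    """Raised when a trace is too corrupted to preprocess."""


@dataclass(frozen=True)
class PupilConfig:
    """Preprocessing and epoching parameters.

    ``blink_pad_ms`` extends the invalid-sample mask on both sides before
    interpolation; ``working_rate_hz`` is the common analysis rate;
    ``smooth_ms`` (0 disables) applies a moving-average low-pass after
    interpolation.  The epoch spans ``epoch_pre_ms`` before to
    ``epoch_post_ms`` after outcome onset.
    """

    blink_pad_ms: float = 100.0
    working_rate_hz: float = 50.0
    smooth_ms: float = 0.0
    epoch_pre_ms: float = 1000.0
    epoch_post_ms: float = 6000.0
    max_invalid_fraction: float = 0.95
    epoch_interp_threshold: float = 0.5
    subject_trial_threshold: float = 0.5


@dataclass
class PupilTrace:
    """A subject's pupil stream plus outcome-onset events.

    ``events`` columns: trial, valence, received, onset_ms, block,
    volatility.
    """

    subject_id: str
    t_ms: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    events: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.events):
            on = self.events["onset_ms"].to_numpy()
            if on.min() < self.t_ms[0] or on.max() > self.t_ms[-1]:
                raise ValueError("event onsets fall outside the sampled range")


def preprocess_trace(trace: PupilTrace, cfg: PupilConfig = PupilConfig()) -> tuple[PupilTrace, np.ndarray]:
    """Blink-interpolate, optionally smooth, and resample a trace.

    Returns the cleaned trace on a regular grid at the working rate plus a
    boolean per-sample flag marking interpolated samples.
    """
    bad = (~trace.valid.astype(bool)) | (trace.pupil <= 0)
    if bad.mean() > cfg.max_invalid_fraction:
        raise UnprocessableSubjectError(
            f"subject {trace.subject_id}: {bad.mean():.0%} of samples invalid"
        )
    pad = max(1, int(round(cfg.blink_pad_ms / 1000.0 * trace.sampling_rate)))
    if bad.any():
        kernel = np.ones(2 * pad + 1)
        bad = np.convolve(bad.astype(float), kernel, mode="same") > 0
    good_idx = np.flatnonzero(~bad)
    if good_idx.size == 0:
        raise UnprocessableSubjectError(f"subject {trace.subject_id}: no valid samples after padding")
    pupil = trace.pupil.astype(float).copy()
    if bad.any():
        pupil = np.interp(np.arange(pupil.size), good_idx, pupil[good_idx])
    if cfg.smooth_ms > 0:
        w = max(1, int(round(cfg.smooth_ms / 1000.0 * trace.sampling_rate)))
        pupil = np.convolve(pupil, np.ones(w) / w, mode="same")

    if abs(trace.sampling_rate - cfg.working_rate_hz) < 1e-9:
        t_new, p_new, interp_new = trace.t_ms, pupil, bad
    else:
        step = 1000.0 / cfg.working_rate_hz
        t_new = np.arange(trace.t_ms[0], trace.t_ms[-1] + 1e-9, step)
        p_new = np.interp(t_new, trace.t_ms, pupil)
        interp_new = np.interp(t_new, trace.t_ms, bad.astype(float)) > 0
    clean = PupilTrace(
        subject_id=trace.subject_id,
        t_ms=t_new,
        pupil=p_new,
        valid=np.ones(p_new.size, dtype=bool),
        sampling_rate=cfg.working_rate_hz,
        events=trace.events,
    )
    return clean, interp_new


def epoch_window(cfg: PupilConfig) -> tuple[int, int, int]:
    """(samples before onset, samples after, epoch length)."""
    rate = cfg.working_rate_hz
    pre = int(round(cfg.epoch_pre_ms / 1000.0 * rate))
    post = int(round(cfg.epoch_post_ms / 1000.0 * rate))
    return pre, post, pre + post + 1


def epoch_outcomes(
    clean: PupilTrace, interp: np.ndarray, cfg: PupilConfig = PupilConfig()
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cut baseline-corrected outcome-locked epochs.

    Returns an (n_epochs, epoch_len) matrix and a metadata frame (trial,
    valence, received, volatility, interp_fraction, baseline).  Events
    whose window exceeds the trace bounds are dropped.
    """
    pre, post, n_len = epoch_window(cfg)
    rate = clean.sampling_rate
    t0 = clean.t_ms[0]
    rows, mats = [], []
    for ev in clean.events.itertuples(index=False):
        centre = int(round((ev.onset_ms - t0) / 1000.0 * rate))
        lo, hi = centre - pre, centre + post + 1
        if lo < 0 or hi > clean.pupil.size:
            continue  # partial epoch
        seg = clean.pupil[lo:hi]
        baseline = float(seg[:pre].mean())
        mats.append(seg - baseline)
        rows.append(
            {
                "trial": ev.trial,
                "valence": ev.valence,
                "received": bool(ev.received),
                "volatility": ev.volatility,
                "interp_fraction": float(interp[lo:hi].mean()),
                "baseline": baseline,
            }
        )
    epochs = np.vstack(mats) if mats else np.empty((0, n_len))
    return epochs, pd.DataFrame(rows)


def apply_exclusions(
    epochs: np.ndarray, meta: pd.DataFrame, cfg: PupilConfig = PupilConfig()
) -> tuple[np.ndarray, pd.DataFrame, bool]:
    """Apply the interpolation-based exclusion rules.

    Epochs with more than ``epoch_interp_threshold`` of their samples
    interpolated are dropped.  The subject is flagged for removal when
    more than ``subject_trial_threshold`` of the task trials exceed that
    interpolation level (a trial's interpolation is the mean over its
    outcome epochs).  Both rules read the same per-epoch fractions, so
    their order cannot change the result.
    """
    if len(meta) == 0:
        return epochs, meta, True
    bad_epoch = meta["interp_fraction"].to_numpy() > cfg.epoch_interp_threshold
    trial_frac = meta.groupby("trial")["interp_fraction"].mean()
    subject_out = bool((trial_frac > cfg.epoch_interp_threshold).mean() > cfg.subject_trial_threshold)
    keep = ~bad_epoch
    return epochs[keep], meta.loc[keep].reset_index(drop=True), subject_out


@dataclass
class ConditionSeries:
    """Per-subject condition contrasts.

    ``cells``: receipt-minus-non-receipt mean series per
    (valence, volatility); ``subtraction``: per valence, the volatile
    minus stable cell.  ``complete`` is False when any cell is empty.
    """

    subject_id: str
    cells: dict
    subtraction: dict
    complete: bool


def condition_timeseries(epochs: np.ndarray, meta: pd.DataFrame, subject_id: str = "") -> ConditionSeries:
    """Collapse epochs to the four condition contrasts and the two
    volatile-minus-stable subtraction series."""
    cells = {}
    complete = True
    for valence in ("win", "loss"):
        for vol in ("volatile", "stable"):
            sel = (meta["valence"] == valence) & (meta["volatility"] == vol)
            rec = sel & meta["received"]
            non = sel & ~meta["received"]
            if rec.sum() == 0 or non.sum() == 0:
                cells[(valence, vol)] = None
                complete = False
            else:
                cells[(valence, vol)] = epochs[rec.to_numpy()].mean(axis=0) - epochs[non.to_numpy()].mean(axis=0)
    subtraction = {}
    for valence in ("win", "loss"):
        v, s = cells[(valence, "volatile")], cells[(valence, "stable")]
        subtraction[valence] = (v - s) if (v is not None and s is not None) else None
    return ConditionSeries(subject_id=subject_id, cells=cells, subtraction=subtraction, complete=complete)


# ---------------------------------------------------------------------------
# permutation inference


@dataclass(frozen=True)
class ClusterResult:
    effect: str
    start_ms: float
    end_ms: float
    mass: float
    p: float


@dataclass
class ClusterTestReport:
    clusters: list[ClusterResult]
    pointwise_F: dict
    pointwise_p: dict
    times_ms: np.ndarray
    n_perm: int


def _qr_basis(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10
    return Q[:, keep]


def _group_design(groups: np.ndarray) -> tuple[np.ndarray, int]:
    levels = sorted(pd.unique(groups))
    n = groups.size
    X = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        X[groups == lev, j] = 1.0
    X[groups == levels[-1], :] = -1.0
    return X, len(levels)


def _pointwise_F(Y1: np.ndarray, Y2: np.ndarray, G: np.ndarray, n_groups: int):
    """Pointwise split-plot F series for (group, valence, group:valence).

    Y1: subject-mean series (n, T); Y2: half the valence difference
    (n, T); G: effect-coded group columns.
    """
    n, T = Y1.shape
    ones = np.ones((n, 1))
    Q_full = _qr_basis(np.hstack([ones, G]))
    Q_int = ones / np.sqrt(n)
    Q_grp = _qr_basis(G)  # reduced design without the intercept
    df_e = n - n_groups

    def sse(Y, Q):
        return np.sum(Y * Y, axis=0) - np.sum((Q.T @ Y) ** 2, axis=0)

    sse1_full = sse(Y1, Q_full)
    sse2_full = sse(Y2, Q_full)
    dfg = n_groups - 1

    def ratio(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        return np.nan_to_num(out, nan=0.0, posinf=np.inf)  # 0/0: no variation at all

    F_group = ratio((sse(Y1, Q_int) - sse1_full) / dfg, sse1_full / df_e)
    F_val = ratio(sse(Y2, Q_grp) - sse2_full, sse2_full / df_e)
    F_gxv = ratio((sse(Y2, Q_int) - sse2_full) / dfg, sse2_full / df_e)
    return {
        "group": (F_group, dfg, df_e),
        "valence": (F_val, 1, df_e),
        "group:valence": (F_gxv, dfg, df_e),
    }


def _clusters(sig: np.ndarray, F: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal contiguous runs of pointwise significance with their mass."""
    out = []
    i = 0
    T = sig.size
    while i < T:
        if sig[i]:
            j = i
            while j + 1 < T and sig[j + 1]:
                j += 1
            out.append((i, j, float(F[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def cluster_permutation_test(
    series: np.ndarray,
    groups,
    times_ms: np.ndarray,
    n_perm: int = 1000,
    alpha_point: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterTestReport:
    """Cluster-mass permutation test of group, valence and their
    interaction on per-subject valence series.

    ``series`` has shape (n_subjects, 2, T): one averaged series per
    subject per valence (win first).  The null is built by permuting
    group labels across subjects and flipping valence labels within
    subjects, recording the maximal cluster mass per effect.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse cluster p-values", RuntimeWarning)
    rng = rng or np.random.default_rng(0)
    series = np.asarray(series, dtype=float)
    groups = np.asarray(groups)
    n, two, T = series.shape
    assert two == 2
    Y1 = series.mean(axis=1)
    Y2 = (series[:, 0, :] - series[:, 1, :]) / 2.0
    G, n_groups = _group_design(groups)

    obs = _pointwise_F(Y1, Y2, G, n_groups)
    obs_clusters = {}
    pointwise_p = {}
    for eff, (F, dfn, dfd) in obs.items():
        p = stats.f.sf(F, dfn, dfd)
        pointwise_p[eff] = p
        obs_clusters[eff] = _clusters(p < alpha_point, F)

    null_max = {eff: np.zeros(n_perm) for eff in obs}
    crit = {eff: stats.f.isf(alpha_point, dfn, dfd) for eff, (_, dfn, dfd) in obs.items()}
    for k in range(n_perm):
        perm_groups = groups[rng.permutation(n)]
        signs = rng.choice([-1.0, 1.0], size=n)
        Gp, _ = _group_design(perm_groups)
        Fp = _pointwise_F(Y1, signs[:, None] * Y2, Gp, n_groups)
        for eff, (F, dfn, dfd) in Fp.items():
            cl = _clusters(F > crit[eff], F)
            null_max[eff][k] = max((m for *_, m in cl), default=0.0)

    clusters = []
    for eff, cl in obs_clusters.items():
        for i, j, mass in cl:
            p = (1.0 + np.sum(null_max[eff] >= mass)) / (n_perm + 1.0)
            clusters.append(
                ClusterResult(effect=eff, start_ms=float(times_ms[i]), end_ms=float(times_ms[j]), mass=mass, p=float(p))
            )
    return ClusterTestReport(
        clusters=clusters,
        pointwise_F={e: v[0] for e, v in obs.items()},
        pointwise_p=pointwise_p,
        times_ms=np.asarray(times_ms),
        n_perm=n_perm,
    )


def window_permutation_test(
    series: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
    groups,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation test of a group effect on window-averaged series.

    Averages each subject's series over ``window_ms``, computes the
    one-way between-group F, and compares it with the label-permutation
    null.  Returns (observed F, permutation p).
    """
    rng = rng or np.random.default_rng(0)
    series = np.asarray(series, dtype=float)
    groups = np.asarray(groups)
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("window contains no timepoints")
    x = series[:, sel].mean(axis=1)

    def f_stat(g):
        gs = [x[g == lev] for lev in pd.unique(g)]
        grand = x.mean()
        ssb = sum(v.size * (v.mean() - grand) ** 2 for v in gs)
        ssw = sum(((v - v.mean()) ** 2).sum() for v in gs)
        dfb, dfw = len(gs) - 1, x.size - len(gs)
        if ssw == 0:
            return 0.0 if ssb <= 1e-30 else np.inf
        return (ssb / dfb) / (ssw / dfw)

    F_obs = f_stat(groups)
    count = 0
    for _ in range(n_perm):
        if f_stat(groups[rng.permutation(groups.size)]) >= F_obs:
            count += 1
    # all-equal data: every permutation ties the observed statistic
    if F_obs == 0.0:
        return 0.0, 1.0
    return float(F_obs), (1.0 + count) / (n_perm + 1.0)


def pupil_behaviour_correlation(
    window_means: pd.Series | dict,
    adjustments: pd.Series | dict,
    groups: pd.Series | dict,
    min_n: int = 4,
) -> pd.DataFrame:
    """Within-group Pearson correlations between a pupil window mean and
    the learning-rate adjustment, plus pairwise Fisher r-to-z contrasts.

    Inputs are aligned by subject id (Series index or dict key).  Groups
    with fewer than ``min_n`` matched subjects are skipped.
    """
    wm = pd.Series(window_means, dtype=float)
    adj = pd.Series(adjustments, dtype=float)
    grp = pd.Series(groups)
    common = wm.index.intersection(adj.index).intersection(grp.index)
    wm, adj, grp = wm[common], adj[common], grp[common]

    per_group = {}
    rows = []
    for g in sorted(grp.unique()):
        sel = grp == g
        n = int(sel.sum())
        if n < min_n:
            rows.append({"kind": "correlation", "group": g, "n": n, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(wm[sel], adj[sel])
        per_group[g] = (float(r), n)
        rows.append({"kind": "correlation", "group": g, "n": n, "r": float(r), "p": float(p)})
    names = sorted(per_group)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            r1, n1 = per_group[g1]
            r2, n2 = per_group[g2]
            cmp = fisher_compare(r1, n1, r2, n2)
            rows.append(
                {"kind": "fisher", "group": f"{g1} vs {g2}", "n": n1 + n2, "r": np.nan, "p": cmp.p, "z": cmp.z}
            )
    return pd.DataFrame(rows)
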
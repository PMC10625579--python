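"""Behavioural statistics for the volatility task.

Covers the analysis chain applied to choice data: exclusion of
non-learners (subjects whose final total never exceeds the 1.50 stake),
switch/stay proportions per valence x volatility cell (logit-transformed
with a continuity correction), learning-rate adjustment summaries from
fitted agents, mixed factorial ANOVAs with Greenhouse-Geisser correction,
Welch and one-sample t-tests, and Fisher r-to-z comparison of independent
correlations.

Throughout, the "volatile" cell for a valence pools block 1 (both
valences volatile) with the block in which only that valence is volatile;
the "stable" cell is the remaining block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agents import START_MONEY, AgentParams, SubjectDataset
from .splitplot import mixed_anova

__all__ = [
    "exclude_nonlearners",
    "compute_stay_cells",
    "stay_table",
    "mixed_anova",
    "one_sample_t",
    "one_sample_t_from_stats",
    "welch_t",
    "fisher_compare",
    "CorrelationComparison",
    "adjustment_table",
    "adjustment_long",
]


def exclude_nonlearners(datasets: list[SubjectDataset]) -> tuple[list[SubjectDataset], list[SubjectDataset]]:
    """Drop subjects showing no evidence of learning.

    A subject is excluded iff their final monetary total is the same as or
    less than the 1.50 they started with.
    """
    kept, excluded = [], []
    for d in datasets:
        if "money_after" not in d.choices.columns:
            raise ValueError(f"subject {d.subject_id}: money trajectory missing")
        (excluded if d.final_money <= START_MONEY + 1e-9 else kept).append(d)
    return kept, excluded


def _volatility_masks(dataset: SubjectDataset) -> dict[str, np.ndarray]:
    """Per-trial boolean mask of whether each valence is volatile."""
    block = dataset.schedule.trials["block"].to_numpy()
    spec_by_block = {b.index: b for b in dataset.schedule.blocks}
    return {
        "win": np.array([spec_by_block[int(b)].win_condition == "volatile" for b in block]),
        "loss": np.array([spec_by_block[int(b)].loss_condition == "volatile" for b in block]),
    }


def compute_stay_cells(dataset: SubjectDataset, continuity: float = 0.5) -> pd.DataFrame:
    """Stay statistics for the four valence x volatility cells.

    For each valence, trials on which the chosen shape carried that
    outcome are selected (excluding each block's last trial, which has no
    next choice within the same stimulus pair); "stay" means repeating
    the choice on the next trial.  Proportions get the add-half
    continuity correction (k + c) / (n + 2c) before the logit, keeping
    logits finite at 0 and 1.  Cells with no qualifying trial are
    returned with NaN statistics.
    """
    t = dataset.schedule.trials
    c = dataset.choices
    chose = c["chose_A"].to_numpy(dtype=bool)
    block = t["block"].to_numpy()
    last_of_block = np.zeros(len(t), dtype=bool)
    last_of_block[np.flatnonzero(np.diff(block) != 0)] = True
    last_of_block[-1] = True
    stay = np.zeros(len(t), dtype=bool)
    stay[:-1] = chose[1:] == chose[:-1]
    vol = _volatility_masks(dataset)

    received = {
        "win": c["win_received"].to_numpy(dtype=bool),
        "loss": c["loss_received"].to_numpy(dtype=bool),
    }
    rows = []
    for valence in ("win", "loss"):
        for volatility, mask in (("volatile", vol[valence]), ("stable", ~vol[valence])):
            use = received[valence] & mask & ~last_of_block
            n = int(use.sum())
            if n == 0:
                prop = lgt = np.nan
            else:
                k = int((stay & use).sum())
                prop = (k + continuity) / (n + 2 * continuity)
                lgt = float(np.log(prop / (1 - prop)))
            rows.append(
                {
                    "subject_id": dataset.subject_id,
                    "group": dataset.group,
                    "order": dataset.order,
                    "valence": valence,
                    "volatility": volatility,
                    "n_outcome_trials": n,
                    "stay_proportion": prop,
                    "stay_logit": lgt,
                }
            )
    return pd.DataFrame(rows)


def stay_table(datasets: list[SubjectDataset]) -> pd.DataFrame:
    """Long-format stay statistics for a cohort (input to the mixed ANOVA)."""
    return pd.concat([compute_stay_cells(d) for d in datasets], ignore_index=True)


# ---------------------------------------------------------------------------
# t-tests and correlation comparison


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample t-test; returns (t, df, two-sided p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one_sample_t needs n >= 2")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, mu0)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def one_sample_t_from_stats(mean: float, sd: float, n: int, mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample t from summary statistics (mean, sd, n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("zero variance")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    return float(t), df, float(2 * stats.t.sf(abs(t), df))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's t-test (unequal variances); returns (t, Welch df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs n >= 2 in both samples")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    df = (vx / x.size + vy / y.size) ** 2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z1: float
    z2: float
    z: float
    p: float


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent Pearson correlations via Fisher's r-to-z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("fisher_compare needs n > 3 in both groups")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return CorrelationComparison(r1, n1, r2, n2, float(z1), float(z2), float(z), p)


# ---------------------------------------------------------------------------
# learning-rate adjustment


def _condition_alphas(params: AgentParams, order: str) -> dict[str, float]:
    """Collapse a (block, valence) learning-rate grid to condition cells.

    The volatile learning rate for a valence averages block 1 with the
    block in which only that valence is volatile; the stable rate is the
    remaining block's.
    """
    if order == "win_volatile_second":
        win_vol_b, loss_vol_b = 1, 2  # 0-based block indices
    elif order == "loss_volatile_second":
        win_vol_b, loss_vol_b = 2, 1
    else:
        raise ValueError(f"unknown block order {order!r}")
    a = params.alpha
    return {
        "alpha_volatile_win": float((a[0, 0] + a[win_vol_b, 0]) / 2),
        "alpha_stable_win": float(a[loss_vol_b, 0]),
        "alpha_volatile_loss": float((a[0, 1] + a[loss_vol_b, 1]) / 2),
        "alpha_stable_loss": float(a[win_vol_b, 1]),
    }


def adjustment_table(subjects: list[tuple[SubjectDataset, AgentParams]]) -> pd.DataFrame:
    """Per-subject learning-rate adjustment (volatile minus stable, per
    valence) from fitted or true parameters, plus group/order labels."""
    rows = []
    for ds, params in subjects:
        cond = _condition_alphas(params, ds.order)
        adj_win = cond["alpha_volatile_win"] - cond["alpha_stable_win"]
        adj_loss = cond["alpha_volatile_loss"] - cond["alpha_stable_loss"]
        rows.append(
            {
                "subject_id": ds.subject_id,
                "group": ds.group,
                "order": ds.order,
                **cond,
                "adjustment_win": adj_win,
                "adjustment_loss": adj_loss,
                "mean_adjustment": (adj_win + adj_loss) / 2,
            }
        )
    return pd.DataFrame(rows)


def adjustment_long(adj: pd.DataFrame) -> pd.DataFrame:
    """Stack the per-valence adjustments into long format (one row per
    subject x valence), the shape used by the adjustment ANOVA and the
    valence-stacked one-sample t-tests."""
    long = adj.melt(
        id_vars=["subject_id", "group", "order"],
        value_vars=["adjustment_win", "adjustment_loss"],
        var_name="valence",
        value_name="adjustment",
    )
    long["valence"] = long["valence"].str.replace("adjustment_", "", regex=False)
    return long
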
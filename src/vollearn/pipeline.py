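"""End-to-end reproduction pipeline.

``run_pipeline`` chains every stage on a synthetic cohort (or one read
from disk): non-learner exclusion, model fitting, behavioural statistics
(stay ANOVA, adjustment ANOVA, block-1 ANOVA, per-group one-sample
t-tests), the pupillometry cluster-permutation analysis, and the
pupil-behaviour correlation, collecting every statistic into a results
bundle plus a human-readable report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import WINNING_MODEL
from .behaviour import (
    adjustment_long,
    adjustment_table,
    exclude_nonlearners,
    mixed_anova,
    one_sample_t,
    stay_table,
)
from .cohort import CohortConfig, CohortData, simulate_cohort
from .fitting import compare_models, fit_map
from .io import RunConfig, stage_rng, stage_seed, write_cohort
from .pupil import (
    PupilConfig,
    apply_exclusions,
    cluster_permutation_test,
    condition_timeseries,
    epoch_outcomes,
    epoch_window,
    preprocess_trace,
    pupil_behaviour_correlation,
    window_permutation_test,
)

log = logging.getLogger("vollearn")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    tables: dict = field(default_factory=dict)
    report: str = ""

    def __getitem__(self, key):
        return self.tables[key]


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[stage: {stage}] {err}")
        self.stage = stage


def run_pipeline(config: RunConfig | None = None, cohort: CohortData | None = None) -> PipelineResult:
    """Run every analysis stage and return the results bundle.

    With no ``cohort`` supplied, a synthetic one is simulated from the
    config's presets.  All randomness derives from the master seed plus
    the stage name.  Writes tables and a text report to ``config.outdir``
    when set.
    """
    config = config or RunConfig()
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    res = PipelineResult()
    stage = "simulate-cohort"
    try:
        if cohort is None:
            seed = stage_seed(config.master_seed, stage)
            log.info("stage %s: seed %d", stage, seed)
            cohort = simulate_cohort(
                CohortConfig(presets=config.presets(), master_seed=seed, simulate_pupil=config.simulate_pupil)
            )
        res.tables["manifest"] = cohort.manifest

        stage = "exclusions"
        kept, excluded = exclude_nonlearners(cohort.datasets)
        res.tables["excluded_nonlearners"] = pd.DataFrame(
            {"subject_id": [d.subject_id for d in excluded], "final_money": [d.final_money for d in excluded]}
        )
        log.info("stage %s: kept %d, excluded %d non-learners", stage, len(kept), len(excluded))

        stage = "fit"
        rng = stage_rng(config.master_seed, stage)
        fits = [fit_map(d, WINNING_MODEL, n_restarts=config.n_restarts, rng=rng) for d in kept]
        res.tables["fits"] = pd.DataFrame(
            [
                {
                    "subject_id": f.subject_id,
                    "model": f.model,
                    **{f"alpha_b{b+1}_{v}": f.params.alpha[b, vi] for b in range(3) for vi, v in enumerate(("win", "loss"))},
                    "beta": f.params.beta,
                    "bias": f.params.bias,
                    "log_lik": f.log_lik,
                }
                for f in fits
            ]
        )

        if config.run_model_comparison:
            stage = "compare-models"
            cmp_rng = stage_rng(config.master_seed, stage)
            comparison = compare_models(kept, n_mc=config.n_mc, rng=cmp_rng, n_restarts=2, em_iters=2)
            res.tables["model_comparison"] = comparison.table

        stage = "behaviour-stats"
        stays = stay_table(kept)
        res.tables["stay_cells"] = stays
        res.tables["stay_anova"] = mixed_anova(
            stays, dv="stay_logit", within=["volatility", "valence"], between=["group", "order"], subject="subject_id"
        )
        pairs = [(d, f.params) for d, f in zip(kept, fits)]
        adj = adjustment_table(pairs)
        res.tables["adjustments"] = adj
        long = adjustment_long(adj)
        res.tables["adjustment_anova"] = mixed_anova(
            long, dv="adjustment", within=["valence"], between=["group", "order"], subject="subject_id"
        )
        block1 = pd.concat(
            [
                pd.DataFrame(
                    {
                        "subject_id": d.subject_id,
                        "group": d.group,
                        "order": d.order,
                        "valence": ["win", "loss"],
                        "alpha_block1": f.params.alpha[0],
                    }
                )
                for d, f in zip(kept, fits)
            ],
            ignore_index=True,
        )
        res.tables["block1_anova"] = mixed_anova(
            block1, dv="alpha_block1", within=["valence"], between=["group", "order"], subject="subject_id"
        )
        ts = []
        for g, sub in long.groupby("group"):
            t, df, p = one_sample_t(sub["adjustment"].to_numpy())
            m, sd = sub["adjustment"].mean(), sub["adjustment"].std(ddof=1)
            ts.append({"group": g, "t": t, "df": df, "p": p, "mean": m, "sd": sd, "n": len(sub)})
        res.tables["adjustment_one_sample_t"] = pd.DataFrame(ts)

        corr_rows = None
        if cohort.traces:
            stage = "pupil"
            rng = stage_rng(config.master_seed, stage)
            pcfg = PupilConfig()
            series, groups, sids = [], [], []
            win_means = {}
            pre, post, _ = epoch_window(pcfg)
            times = (np.arange(pre + post + 1) - pre) * (1000.0 / pcfg.working_rate_hz)
            kept_ids = {d.subject_id: d.group for d in kept}
            for trace in cohort.traces:
                if trace.subject_id not in kept_ids:
                    continue
                clean, interp = preprocess_trace(trace, pcfg)
                epochs, meta = epoch_outcomes(clean, interp, pcfg)
                epochs, meta, subject_out = apply_exclusions(epochs, meta, pcfg)
                if subject_out:
                    continue
                cond = condition_timeseries(epochs, meta, subject_id=trace.subject_id)
                if not cond.complete:
                    continue
                series.append(np.stack([cond.subtraction["win"], cond.subtraction["loss"]]))
                groups.append(kept_ids[trace.subject_id])
                sids.append(trace.subject_id)
                w0, w1 = config.correlation_window_ms
                sel = (times >= w0) & (times <= w1)
                win_means[trace.subject_id] = float(cond.subtraction["win"][sel].mean())
            if len(series) >= 8:
                report = cluster_permutation_test(
                    np.stack(series), np.array(groups), times, n_perm=config.n_perm, rng=rng
                )
                res.tables["clusters"] = pd.DataFrame(
                    [
                        {"effect": c.effect, "start_ms": c.start_ms, "end_ms": c.end_ms, "mass": c.mass, "p": c.p}
                        for c in report.clusters
                    ]
                )
                win_series = np.stack(series)[:, 0, :]
                F, p = window_permutation_test(
                    win_series, times, config.correlation_window_ms, np.array(groups), n_perm=config.n_perm, rng=rng
                )
                res.tables["window_test"] = pd.DataFrame(
                    [{"effect": "group", "window": str(config.correlation_window_ms), "F": F, "p": p}]
                )
                stage = "correlation"
                adj_win = adj.set_index("subject_id")["adjustment_win"]
                corr_rows = pupil_behaviour_correlation(
                    pd.Series(win_means), adj_win, pd.Series({d.subject_id: d.group for d in kept})
                )
                res.tables["pupil_behaviour_correlation"] = corr_rows
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - stage-tagged re-raise
        raise StageError(stage, err) from err

    res.report = _render_report(res)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in res.tables.items():
            if isinstance(table, pd.DataFrame):
                table.to_csv(out / f"{name}.csv", index=False)
        (out / "report.txt").write_text(res.report)
        write_cohort(cohort, out / "cohort")
    return res


def _render_report(res: PipelineResult) -> str:
    lines = ["volatility-task analysis report", "=" * 34, ""]
    for name in (
        "excluded_nonlearners",
        "model_comparison",
        "stay_anova",
        "adjustment_anova",
        "block1_anova",
        "adjustment_one_sample_t",
        "clusters",
        "window_test",
        "pupil_behaviour_correlation",
    ):
        if name in res.tables:
            lines.append(f"## {name}")
            lines.append(res.tables[name].round(4).to_string(index=False))
            lines.append("")
    return "\n".join(lines)
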
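"""Behavioural statistics: exclusions, switch/stay, t-tests, Fisher r-to-z,
mixed ANOVA (cross-checked against pingouin) and adjustment summaries."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from conftest import toy_schedule
from vollearn.agents import AgentParams, SubjectDataset, WINNING_MODEL
from vollearn.behaviour import (
    adjustment_table,
    compute_stay_cells,
    exclude_nonlearners,
    fisher_compare,
    mixed_anova,
    one_sample_t,
    one_sample_t_from_stats,
    welch_t,
)
from vollearn.cohort import DEFAULT_PRESETS, CohortConfig, GroupPreset, simulate_cohort


def _dataset_with_final_money(final):
    n = 10
    sched = toy_schedule(np.full(n, 0.5), np.full(n, 0.5), np.ones(n, bool), np.zeros(n, bool))
    money = np.linspace(1.5, final, n)
    choices = pd.DataFrame(
        {
            "trial": np.arange(n) + 1,
            "block": 1,
            "chose_A": True,
            "win_received": True,
            "loss_received": False,
            "money_after": money,
        }
    )
    return SubjectDataset("s", "HC", "win_volatile_second", sched, choices)


@pytest.mark.parametrize("final,kept", [(1.50, False), (1.65, True), (1.35, False)])
def test_nonlearner_exclusion_threshold(final, kept):
    k, e = exclude_nonlearners([_dataset_with_final_money(final)])
    assert (len(k) == 1) == kept


def _toy_stay_dataset():
    """Hand-built 10-trial log: 8 win-receipt trials with 6 stays, 4
    loss-receipt trials with 2 stays."""
    chose = np.array([1, 1, 1, 0, 0, 0, 1, 1, 1, 1], dtype=bool)
    win_rec = np.array([1, 1, 1, 1, 1, 1, 1, 1, 0, 0], dtype=bool)
    loss_rec = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0], dtype=bool)
    win_on = np.where(win_rec, chose, ~chose)
    loss_on = np.where(loss_rec, chose, ~chose)
    sched = toy_schedule(np.full(10, 0.5), np.full(10, 0.5), win_on, loss_on,
                         win_condition="volatile", loss_condition="stable")
    money = 1.5 + 0.15 * np.cumsum(win_rec.astype(int) - loss_rec.astype(int))
    choices = pd.DataFrame(
        {"trial": np.arange(10) + 1, "block": 1, "chose_A": chose,
         "win_received": win_rec, "loss_received": loss_rec, "money_after": money}
    )
    return SubjectDataset("toy", "RA", "win_volatile_second", sched, choices)


class TestStayCells:
    def test_hand_counted_proportion_and_logit(self):
        cells = compute_stay_cells(_toy_stay_dataset(), continuity=0.0)
        row = cells[(cells.valence == "win") & (cells.volatility == "volatile")].iloc[0]
        assert row.n_outcome_trials == 8
        assert row.stay_proportion == pytest.approx(0.75)
        assert row.stay_logit == pytest.approx(np.log(3), abs=1e-6)

    def test_half_proportion_gives_zero_logit(self):
        cells = compute_stay_cells(_toy_stay_dataset())
        row = cells[(cells.valence == "loss") & (cells.volatility == "stable")].iloc[0]
        assert row.stay_proportion == pytest.approx(0.5)
        assert row.stay_logit == pytest.approx(0.0, abs=1e-9)

    def test_all_stays_have_finite_logit(self, dataset):
        ds = _toy_stay_dataset()
        ds.choices["chose_A"] = True
        cells = compute_stay_cells(ds)
        assert (cells.dropna().stay_proportion < 1).all()
        assert np.isfinite(cells.dropna().stay_logit).all()

    def test_empty_cell_flagged_nan(self):
        ds = _toy_stay_dataset()
        ds.choices["loss_received"] = False
        cells = compute_stay_cells(ds)
        loss = cells[cells.valence == "loss"]
        assert loss.stay_proportion.isna().all()


class TestMixedAnova:
    def _random_mixed(self, seed, n_per_group=10, effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, group in enumerate(("a", "b")):
            for i in range(n_per_group):
                sid = f"{group}{i}"
                base = rng.normal()
                for w, cond in enumerate(("x", "y")):
                    rows.append(
                        {"subject_id": sid, "group": group, "cond": cond,
                         "dv": base + rng.normal() + effect * g * w}
                    )
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pingouin_one_between_one_within(self, seed):
        df = self._random_mixed(seed, effect=0.5)
        ours = mixed_anova(df, dv="dv", within=["cond"], between=["group"], subject="subject_id")
        ref = pg.mixed_anova(df, dv="dv", within="cond", between="group", subject="subject_id")
        for theirs, name in (("group", "group"), ("cond", "cond"), ("Interaction", "group:cond")):
            F_ref = float(ref.loc[ref.Source == theirs, "F"].iloc[0])
            row = ours[ours.effect == name].iloc[0]
            assert row.F == pytest.approx(F_ref, rel=1e-6)

    def test_matches_pingouin_rm_anova_with_gg(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(15):
            base = rng.normal(0, 1)
            scale = [1.0, 1.5, 3.0]  # heteroscedastic cells -> epsilon < 1
            for w, cond in enumerate(("x", "y", "z")):
                rows.append({"subject_id": f"s{i}", "cond": cond, "dv": base + rng.normal(0, scale[w]) + 0.4 * w})
        df = pd.DataFrame(rows)
        ours = mixed_anova(df, dv="dv", within=["cond"], between=[], subject="subject_id").iloc[0]
        ref = pg.rm_anova(df, dv="dv", within="cond", subject="subject_id", correction=True)
        assert ours.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert ours.gg_epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-6)
        assert ours.p_gg == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-4)

    def test_two_level_within_has_unit_epsilon(self):
        df = self._random_mixed(7)
        ours = mixed_anova(df, dv="dv", within=["cond"], between=["group"], subject="subject_id")
        within_rows = ours[ours.effect.str.contains("cond")]
        assert (within_rows.gg_epsilon == 1.0).all()
        assert np.allclose(within_rows.p, within_rows.p_gg)

    def test_constant_within_difference_zero_F(self):
        df = self._random_mixed(3)
        wide = df.pivot_table(index=["subject_id", "group"], columns="cond", values="dv").reset_index()
        wide["y"] = wide["x"]  # identical across within levels
        long = wide.melt(id_vars=["subject_id", "group"], value_vars=["x", "y"], var_name="cond", value_name="dv")
        ours = mixed_anova(long, dv="dv", within=["cond"], between=["group"], subject="subject_id")
        assert ours[ours.effect == "cond"].F.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_sum_of_squares_additive_on_balanced_between_design(self):
        df = self._random_mixed(9)
        subject_means = df.groupby(["subject_id", "group"])["dv"].mean().reset_index()
        ours = mixed_anova(df, dv="dv", within=["cond"], between=["group"], subject="subject_id")
        row = ours[ours.effect == "group"].iloc[0]
        # between stratum: centred SS of subject means (x cells) decomposes
        total = 2 * ((subject_means.dv - subject_means.dv.mean()) ** 2).sum()
        assert row.ss_effect + row.ss_error == pytest.approx(total)

    def test_small_between_cell_rejected(self):
        df = self._random_mixed(0, n_per_group=1)
        with pytest.raises(ValueError, match="at least 2"):
            mixed_anova(df, dv="dv", within=["cond"], between=["group"], subject="subject_id")


class TestTTests:
    def test_printed_group_t(self):
        t, df, p = one_sample_t_from_stats(0.191, 0.169, 50)
        assert t == pytest.approx(8.00, abs=0.05)
        assert df == 49 and p < 0.001

    def test_third_group_t_from_rounded_inputs(self):
        t, df, p = one_sample_t_from_stats(0.107, 0.195, 64)
        assert t == pytest.approx(4.39, abs=0.01)

    def test_symmetric_values_zero_t(self):
        t, _, p = one_sample_t([-2, -1, 0, 1, 2])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_hand_computation(self):
        # means 2 and 4, variances 1 and 4 -> t = -2/sqrt(5/3), df = 50/17
        t, df, p = welch_t([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-2 / np.sqrt(5 / 3), abs=1e-9)
        assert df == pytest.approx(50 / 17, abs=1e-9)

    def test_welch_antisymmetric(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2) and df1 == pytest.approx(df2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            welch_t([1, 1], [2, 2])


class TestFisherCompare:
    def test_identical_correlations(self):
        res = fisher_compare(0.3, 20, 0.3, 25)
        assert res.z == 0.0 and res.p == pytest.approx(1.0)

    def test_published_style_inputs(self):
        # r = .512 (n 24) vs r = .067 (n 25)
        res = fisher_compare(0.512, 24, 0.067, 25)
        assert res.z == pytest.approx(1.64, abs=0.01)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare(0.5, 3, 0.1, 30)


class TestAdjustment:
    def test_equal_rates_give_zero_adjustment(self, schedule):
        params = AgentParams.from_free(WINNING_MODEL, [0.3] * 6, beta=5.0)
        ds = SubjectDataset("s", "HC", "win_volatile_second", schedule,
                            pd.DataFrame({"trial": [1], "block": [1], "chose_A": [True],
                                          "win_received": [True], "loss_received": [False],
                                          "money_after": [1.65]}))
        adj = adjustment_table([(ds, params)])
        assert adj.adjustment_win.iloc[0] == 0.0
        assert adj.adjustment_loss.iloc[0] == 0.0

    def test_generative_adjustment_recovered_from_true_params(self):
        preset = GroupPreset(name="RA", n_subjects=40, adjustment_mean=0.191, adjustment_sd=0.169)
        cohort = simulate_cohort(CohortConfig(presets=(preset,), master_seed=5, simulate_pupil=False))
        adj = adjustment_table([(d, d.true_params) for d in cohort.datasets])
        se = 0.169 / np.sqrt(2 * 40)
        assert adj.mean_adjustment.mean() == pytest.approx(0.191, abs=2 * se)

    def test_ra_exceeds_hc_at_preset_effect_sizes(self):
        """Headline direction: generative RA mean adjustment exceeds HC in
        at least 90% of replicate cohorts."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            cohort = simulate_cohort(
                CohortConfig(
                    presets=tuple(p for p in DEFAULT_PRESETS if p.name in ("RA", "HC")),
                    master_seed=seed,
                    simulate_pupil=False,
                )
            )
            adj = adjustment_table([(d, d.true_params) for d in cohort.datasets])
            means = adj.groupby("group").mean_adjustment.mean()
            hits += means["RA"] > means["HC"]
        assert hits / n_rep >= 0.90
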
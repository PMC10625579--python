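"""Pupil preprocessing, epoching, condition contrasts and permutation
inference."""

import numpy as np
import pandas as pd
import pytest

from vollearn.pupil import (
    PupilConfig,
    PupilTrace,
    UnprocessableSubjectError,
    apply_exclusions,
    cluster_permutation_test,
    condition_timeseries,
    epoch_outcomes,
    epoch_window,
    preprocess_trace,
    pupil_behaviour_correlation,
    window_permutation_test,
)

RATE = 50.0
CFG = PupilConfig()


def make_trace(pupil, valid=None, events=None, rate=RATE):
    n = len(pupil)
    t = np.arange(n) * (1000.0 / rate)
    valid = np.ones(n, dtype=bool) if valid is None else valid
    events = events if events is not None else pd.DataFrame(
        columns=["trial", "valence", "received", "onset_ms", "block", "volatility"]
    )
    return PupilTrace("s", t, np.asarray(pupil, float), valid, rate, events)


def one_event(onset_ms, valence="win", received=True, volatility="volatile", trial=1):
    return pd.DataFrame(
        [{"trial": trial, "valence": valence, "received": received, "onset_ms": onset_ms,
          "block": 1, "volatility": volatility}]
    )


class TestPreprocess:
    def test_fully_valid_trace_unchanged(self):
        rng = np.random.default_rng(0)
        trace = make_trace(5 + rng.normal(0, 0.1, 500))
        clean, interp = preprocess_trace(trace, CFG)
        assert np.array_equal(clean.pupil, trace.pupil)
        assert not interp.any()

    def test_blink_between_constant_segments_fills_constant(self):
        pupil = np.full(500, 4.2)
        valid = np.ones(500, dtype=bool)
        pupil[200:210] = 0.0  # 200 ms blink
        valid[200:210] = False
        clean, interp = preprocess_trace(make_trace(pupil, valid), CFG)
        assert np.allclose(clean.pupil, 4.2)
        assert interp[200:210].all()
        # padding extends the interpolated flag ~100 ms on each side
        assert interp[196] and interp[213]

    def test_blink_on_ramp_fills_the_analytic_line(self):
        pupil = np.linspace(3.0, 5.0, 500)
        expected = pupil.copy()
        valid = np.ones(500, dtype=bool)
        pupil[250:265] = 0.0
        valid[250:265] = False
        clean, _ = preprocess_trace(make_trace(pupil, valid), CFG)
        assert np.allclose(clean.pupil, expected, atol=1e-9)

    def test_mostly_invalid_trace_unprocessable(self):
        valid = np.zeros(500, dtype=bool)
        valid[:10] = True
        with pytest.raises(UnprocessableSubjectError):
            preprocess_trace(make_trace(np.ones(500), valid), CFG)

    def test_resamples_to_working_rate(self):
        trace = make_trace(np.sin(np.arange(1000) / 50), rate=250.0)
        clean, interp = preprocess_trace(trace, CFG)
        assert clean.sampling_rate == 50.0
        assert np.allclose(np.diff(clean.t_ms), 20.0)


class TestEpoching:
    def test_epoch_length_spans_seven_seconds(self):
        pre, post, n = epoch_window(CFG)
        assert (pre, post, n) == (50, 300, 351)

    def test_constant_trace_epochs_to_zero(self):
        trace = make_trace(np.full(1000, 6.0), events=one_event(5000.0))
        clean, interp = preprocess_trace(trace, CFG)
        epochs, meta = epoch_outcomes(clean, interp, CFG)
        assert epochs.shape == (1, 351)
        assert np.allclose(epochs, 0.0)

    def test_step_at_onset_is_zero_then_one(self):
        pupil = np.full(1000, 2.0)
        onset = 5000.0
        pupil[int(onset / 20):] += 1.0
        trace = make_trace(pupil, events=one_event(onset))
        clean, interp = preprocess_trace(trace, CFG)
        epochs, _ = epoch_outcomes(clean, interp, CFG)
        pre, _, _ = epoch_window(CFG)
        assert np.allclose(epochs[0, :pre], 0.0)
        assert np.allclose(epochs[0, pre:], 1.0)

    def test_partial_epoch_dropped(self):
        trace = make_trace(np.full(100, 2.0), events=one_event(500.0))
        clean, interp = preprocess_trace(trace, CFG)
        epochs, meta = epoch_outcomes(clean, interp, CFG)
        assert len(meta) == 0

    def test_shift_equivariance(self):
        """Adding a constant to the raw diameters changes nothing after
        baseline subtraction."""
        rng = np.random.default_rng(1)
        pupil = 5 + rng.normal(0, 0.2, 2000)
        ev = pd.concat([one_event(8000.0), one_event(22000.0, received=False, trial=2)], ignore_index=True)
        e1, _ = epoch_outcomes(*preprocess_trace(make_trace(pupil, events=ev), CFG), CFG)
        e2, _ = epoch_outcomes(*preprocess_trace(make_trace(pupil + 3.7, events=ev), CFG), CFG)
        assert np.allclose(e1, e2, atol=1e-9)


class TestExclusions:
    def _meta(self, fractions, trials=None):
        trials = trials if trials is not None else np.arange(len(fractions)) + 1
        return pd.DataFrame(
            {"trial": trials, "valence": "win", "received": True, "volatility": "volatile",
             "interp_fraction": fractions, "baseline": 0.0}
        )

    @pytest.mark.parametrize("frac,kept", [(0.55, 0), (0.45, 1)])
    def test_epoch_interp_threshold(self, frac, kept):
        meta = self._meta([frac])
        epochs = np.zeros((1, 351))
        e, m, _ = apply_exclusions(epochs, meta, CFG)
        assert len(m) == kept

    def test_subject_removed_when_most_trials_bad(self):
        fr = [0.8] * 6 + [0.1] * 4  # 60% of trials above threshold
        _, _, out = apply_exclusions(np.zeros((10, 351)), self._meta(fr))
        assert out

    def test_subject_kept_when_few_trials_bad(self):
        fr = [0.8] * 4 + [0.1] * 6
        _, _, out = apply_exclusions(np.zeros((10, 351)), self._meta(fr))
        assert not out


class TestConditionSeries:
    def _meta(self, valences, vols, received):
        return pd.DataFrame(
            {"trial": np.arange(len(valences)) + 1, "valence": valences, "received": received,
             "volatility": vols, "interp_fraction": 0.0, "baseline": 0.0}
        )

    def test_identical_receipt_and_nonreceipt_zero(self):
        epochs = np.ones((8, 10))
        meta = self._meta(["win", "win", "loss", "loss"] * 2,
                          ["volatile", "volatile", "volatile", "volatile", "stable", "stable", "stable", "stable"],
                          [True, False] * 4)
        cond = condition_timeseries(epochs, meta)
        assert cond.complete
        for s in cond.subtraction.values():
            assert np.allclose(s, 0.0)

    def test_hand_computed_subtraction(self):
        # win volatile: receipt 2, non-receipt 1 -> contrast 1
        # win stable: receipt 5, non-receipt 1 -> contrast 4; subtraction -3
        rows = [
            ("win", "volatile", True, 2.0), ("win", "volatile", False, 1.0),
            ("win", "stable", True, 5.0), ("win", "stable", False, 1.0),
            ("loss", "volatile", True, 3.0), ("loss", "volatile", False, 0.0),
            ("loss", "stable", True, 1.0), ("loss", "stable", False, 0.0),
        ]
        meta = self._meta([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])
        epochs = np.array([[r[3]] * 4 for r in rows])
        cond = condition_timeseries(epochs, meta)
        assert np.allclose(cond.subtraction["win"], -3.0)
        assert np.allclose(cond.subtraction["loss"], 2.0)

    def test_empty_cell_flags_subject(self):
        meta = self._meta(["win"] * 4, ["volatile"] * 4, [True, False, True, False])
        cond = condition_timeseries(np.ones((4, 10)), meta)
        assert not cond.complete


class TestClusterPermutation:
    def _null_series(self, rng, n=24, T=80):
        from scipy.ndimage import gaussian_filter1d
        x = rng.normal(0, 1, (n, 2, T))
        return gaussian_filter1d(x, sigma=3, axis=-1)

    def test_constant_series_no_clusters(self):
        series = np.ones((12, 2, 40))
        groups = np.repeat(["a", "b", "c"], 4)
        rep = cluster_permutation_test(series, groups, np.arange(40) * 20.0, n_perm=120, rng=np.random.default_rng(0))
        assert rep.clusters == []

    def test_injected_group_effect_detected_in_window(self):
        """A between-group offset at 3x the noise SD over 1000-3000 ms is
        found as a significant group cluster overlapping that window in at
        least 95% of replicates."""
        times = np.arange(-1000, 6001, 20.0)
        win = (times >= 1000) & (times <= 3000)
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            rng = np.random.default_rng(100 + r)
            series = self._null_series(rng, n=24, T=times.size)
            groups = np.repeat(["a", "b", "c"], 8)
            series[8:16, :, win] += 3.0 * series.std()
            rep = cluster_permutation_test(series, groups, times, n_perm=200, rng=rng)
            sig = [c for c in rep.clusters if c.effect == "group" and c.p < 0.05
                   and c.start_ms <= 3000 and c.end_ms >= 1000]
            hits += bool(sig)
        assert hits / n_rep >= 0.95

    def test_cluster_p_in_attainable_range(self):
        rng = np.random.default_rng(5)
        series = self._null_series(rng)
        rep = cluster_permutation_test(series, np.repeat(["a", "b", "c"], 8), np.arange(80) * 20.0,
                                       n_perm=150, rng=rng)
        for c in rep.clusters:
            assert 1 / 151 <= c.p <= 1.0


class TestWindowPermutation:
    def test_all_equal_values_p_one(self):
        series = np.ones((12, 30))
        F, p = window_permutation_test(series, np.arange(30) * 20.0, (0, 600), np.repeat(["a", "b"], 6),
                                       n_perm=99, rng=np.random.default_rng(0))
        assert F == 0.0 and p == 1.0

    def test_complete_separation_minimal_p(self):
        series = np.concatenate([np.zeros((8, 10)), np.ones((8, 10))])
        F, p = window_permutation_test(series, np.arange(10) * 20.0, (0, 200), np.repeat(["a", "b"], 8),
                                       n_perm=199, rng=np.random.default_rng(1))
        assert p == pytest.approx(1 / 200)

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            series = rng.normal(0, 1, (18, 10))
            _, p = window_permutation_test(series, np.arange(10) * 20.0, (0, 200),
                                           np.repeat(["a", "b", "c"], 6), n_perm=99, rng=rng)
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_permutation_test(np.ones((4, 10)), np.arange(10) * 20.0, (900, 950), ["a", "a", "b", "b"])


class TestPupilBehaviourCorrelation:
    def test_perfect_coupling(self):
        ids = [f"s{i}" for i in range(10)]
        x = pd.Series(np.arange(10.0), index=ids)
        res = pupil_behaviour_correlation(x, 2 * x + 1, pd.Series("RA", index=ids))
        assert res[res.kind == "correlation"].r.iloc[0] == pytest.approx(1.0)

    def test_shuffled_pairing_centred_on_zero(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(30)]
        rs = []
        for _ in range(50):
            x = pd.Series(rng.normal(0, 1, 30), index=ids)
            y = pd.Series(rng.normal(0, 1, 30), index=ids)
            res = pupil_behaviour_correlation(x, y, pd.Series("RA", index=ids))
            rs.append(res[res.kind == "correlation"].r.iloc[0])
        assert abs(np.mean(rs)) < 0.1

    def test_small_groups_skipped(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "b3", "b4", "b5"]
        grp = pd.Series(["A"] * 3 + ["B"] * 5, index=ids)
        x = pd.Series(np.arange(8.0), index=ids)
        res = pupil_behaviour_correlation(x, x, grp)
        assert np.isnan(res[(res.kind == "correlation") & (res.group == "A")].r.iloc[0])
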
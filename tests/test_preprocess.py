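"""Preprocessing chain: discard, lag shift, detrend, z-scoring, extraction."""

import numpy as np
import pandas as pd
import pytest

import decnef as dn
from decnef.preprocess import RunSeries


def make_run(signal, tr=2.0, events=None, run_id=0):
    if events is None:
        events = pd.DataFrame(
            columns=["run", "trial", "face_id", "rating", "period", "onset_s", "duration_s"]
        )
    return RunSeries(signal=np.asarray(signal, float), tr_s=tr, run_id=run_id, events=events)


def simple_events(n_trials=1, period="rating", onset0=10.5, spacing=12.0, duration=6.0):
    rows = [
        {
            "run": 0, "trial": k, "face_id": k + 1, "rating": 5,
            "period": period, "onset_s": onset0 + k * spacing, "duration_s": duration,
        }
        for k in range(n_trials)
    ]
    return pd.DataFrame(rows)


class TestDiscard:
    def test_ten_seconds_excludes_five_volumes_of_a_126_volume_run(self):
        run = make_run(np.zeros((2, 126)))
        out = dn.discard_initial(run, 10.0)
        assert out.excluded[:5].all() and not out.excluded[5:].any()
        assert out.n_volumes == 126  # volumes retained for indexing

    def test_zero_seconds_is_identity(self):
        run = make_run(np.arange(20.0).reshape(2, 10))
        out = dn.discard_initial(run, 0.0)
        assert not out.excluded.any()
        np.testing.assert_array_equal(out.signal, run.signal)

    def test_discarding_the_whole_run_is_an_error(self):
        run = make_run(np.zeros((2, 126)))
        with pytest.raises(ValueError, match="no volumes"):
            dn.discard_initial(run, 252.0)

    def test_non_tr_multiple_is_rejected(self):
        run = make_run(np.zeros((2, 126)))
        with pytest.raises(ValueError, match="multiple of TR"):
            dn.discard_initial(run, 3.0)


class TestShift:
    def test_lag_4s_at_tr_2_shifts_by_two_volumes(self):
        run = make_run(np.arange(10.0)[None, :])
        out = dn.shift_hemodynamic(run, 4.0)
        assert out.n_volumes == 8
        np.testing.assert_array_equal(out.signal[0], np.arange(2.0, 10.0))

    def test_zero_lag_is_identity(self):
        run = make_run(np.arange(10.0)[None, :])
        out = dn.shift_hemodynamic(run, 0.0)
        np.testing.assert_array_equal(out.signal, run.signal)

    def test_negative_lag_is_rejected(self):
        run = make_run(np.zeros((1, 10)))
        with pytest.raises(ValueError, match="non-negative"):
            dn.shift_hemodynamic(run, -2.0)

    def test_impulse_moves_to_stimulus_time_by_brute_force(self):
        # impulse at scan volume k must appear at stimulus-time volume k - lag/TR
        for k in (5, 8, 11):
            sig = np.zeros((1, 12))
            sig[0, k] = 1.0
            out = dn.shift_hemodynamic(make_run(sig), 4.0)
            expect = np.zeros(10)
            expect[k - 2] = 1.0
            np.testing.assert_array_equal(out.signal[0], expect)

    def test_excluded_mask_follows_the_shift(self):
        run = dn.discard_initial(make_run(np.zeros((1, 126))), 10.0)
        out = dn.shift_hemodynamic(run, 4.0)
        # scan volumes 0..4 excluded -> stimulus volumes 0..2 after 2-volume shift
        assert out.excluded[:3].all() and not out.excluded[3:].any()


class TestDetrend:
    def test_pure_ramp_leaves_zero_residual(self):
        t = np.arange(30.0)
        run = make_run((2.0 + 0.3 * t)[None, :])
        out = dn.detrend_linear(run)
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-10)

    def test_residual_mean_over_included_volumes_is_zero(self):
        rng = np.random.default_rng(0)
        run = dn.discard_initial(make_run(rng.normal(size=(4, 60))), 10.0)
        out = dn.detrend_linear(run)
        np.testing.assert_allclose(out.signal[:, out.included].mean(axis=1), 0.0, atol=1e-10)

    def test_ramp_plus_sine_matches_least_squares_oracle(self):
        t = np.arange(50.0)
        sig = 1.5 - 0.2 * t + np.sin(t / 3.0)
        out = dn.detrend_linear(make_run(sig[None, :]))
        # brute-force least-squares line on the same volumes
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(X, sig, rcond=None)[0]
        np.testing.assert_allclose(out.signal[0], sig - X @ beta, atol=1e-10)

    def test_fit_ignores_excluded_volumes(self):
        t = np.arange(40.0)
        sig = 0.5 * t
        sig[:5] += 100.0  # equilibration artifact in the discarded window
        run = dn.discard_initial(make_run(sig[None, :], tr=2.0), 10.0)
        out = dn.detrend_linear(run)
        np.testing.assert_allclose(out.signal[0, 5:], 0.0, atol=1e-9)

    def test_too_few_included_volumes_raise(self):
        run = dn.discard_initial(make_run(np.zeros((1, 6))), 8.0)
        with pytest.raises(ValueError, match="at least 3"):
            dn.detrend_linear(run)


class TestZscoreOffline:
    def test_included_volumes_become_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        run = dn.discard_initial(make_run(rng.normal(3.0, 2.0, (3, 60))), 10.0)
        out = dn.zscore_offline(run)
        inc = out.included
        np.testing.assert_allclose(out.signal[:, inc].mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.signal[:, inc].std(axis=1), 1.0, atol=1e-10)

    def test_constant_voxel_is_reported_by_index(self):
        sig = np.vstack([np.random.default_rng(2).normal(size=20), np.full(20, 7.0)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            dn.zscore_offline(make_run(sig))

    def test_matches_brute_force_on_four_voxel_toy_run(self):
        rng = np.random.default_rng(3)
        sig = rng.normal(size=(4, 30))
        run = dn.discard_initial(make_run(sig), 10.0)
        out = dn.zscore_offline(run)
        for v in range(4):
            m, s = sig[v, 5:].mean(), sig[v, 5:].std()
            np.testing.assert_allclose(out.signal[v], (sig[v] - m) / s, atol=1e-12)


class TestZscoreOnline:
    def test_baseline_is_scan_volumes_5_to_14(self):
        rng = np.random.default_rng(4)
        sig = rng.normal(size=(2, 60))
        out = dn.zscore_online(make_run(sig))
        for v in range(2):
            m, s = sig[v, 5:15].mean(), sig[v, 5:15].std()
            np.testing.assert_allclose(out.signal[v], (sig[v] - m) / s, atol=1e-12)
        # the baseline window itself is mean 0, sd 1 after the transform
        np.testing.assert_allclose(out.signal[:, 5:15].mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.signal[:, 5:15].std(axis=1), 1.0, atol=1e-10)

    def test_baseline_window_tracks_the_lag_shift(self):
        rng = np.random.default_rng(5)
        sig = rng.normal(size=(1, 60))
        shifted = dn.shift_hemodynamic(make_run(sig), 4.0)
        out = dn.zscore_online(shifted)
        m, s = sig[0, 5:15].mean(), sig[0, 5:15].std()  # same scan-time window
        np.testing.assert_allclose(out.signal[0], (sig[0, 2:] - m) / s, atol=1e-12)

    def test_differs_from_offline_under_post_baseline_drift(self):
        t = np.arange(60.0)
        sig = np.random.default_rng(6).normal(size=60)
        sig[30:] += 5.0  # late drift the online baseline cannot see
        on = dn.zscore_online(make_run(sig[None, :]))
        off = dn.zscore_offline(make_run(sig[None, :]))
        assert not np.allclose(on.signal, off.signal)

    def test_window_past_run_end_is_an_error(self):
        with pytest.raises(ValueError, match="past the end"):
            dn.zscore_online(make_run(np.zeros((1, 12))))


class TestExtract:
    def test_twenty_trial_run_yields_twenty_rows(self, session12):
        runs, _ = session12
        run = dn.preprocess_offline(runs[0])
        sm = dn.extract_trial_samples(run, "rating")
        assert sm.n_trials == 20
        assert sm.window_volumes == 3  # 6 s at TR 2 s

    def test_window_of_identical_volumes_returns_that_volume(self):
        sig = np.tile(np.array([[2.0], [5.0]]), (1, 20))
        events = simple_events(onset0=10.0)
        sm = dn.extract_trial_samples(make_run(sig, events=events), "rating")
        np.testing.assert_allclose(sm.samples[0], [2.0, 5.0])

    def test_fixation_period_of_induction_trials_is_selectable(self, gt_small, decoder12):
        from decnef.neurofeedback import induction_run_events

        events = induction_run_events(0, np.arange(1, 16), 15)
        sig = np.random.default_rng(7).normal(size=(gt_small.n_voxels, 165))
        sm = dn.extract_trial_samples(make_run(sig, events=events), "fixation")
        assert sm.n_trials == 15
        assert sm.period == "fixation"

    def test_period_past_run_end_is_an_error(self):
        events = simple_events(onset0=36.0)
        with pytest.raises(ValueError, match="extends past"):
            dn.extract_trial_samples(make_run(np.zeros((1, 20)), events=events), "rating")

    def test_non_integer_window_requires_explicit_volumes(self):
        events = simple_events(onset0=10.0, duration=5.5, period="inter_trial")
        run = make_run(np.zeros((1, 30)), events=events)
        with pytest.raises(ValueError, match="window_volumes"):
            dn.extract_trial_samples(run, "inter_trial")
        sm = dn.extract_trial_samples(run, "inter_trial", window_volumes=2)
        assert sm.window_volumes == 2


class TestNormalizeTrainTest:
    def test_training_columns_become_mean_zero_var_one(self, samples12):
        half = samples12.n_trials // 2
        import decnef.decoder as dd

        train = dd._subset(samples12, np.arange(samples12.n_trials) < half)
        test = dd._subset(samples12, np.arange(samples12.n_trials) >= half)
        tr, te = dn.normalize_train_test(train, test)
        np.testing.assert_allclose(tr.samples.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(tr.samples.std(axis=0), 1.0, atol=1e-10)

    def test_test_equal_to_train_is_also_standardized(self, samples12):
        tr, te = dn.normalize_train_test(samples12, samples12)
        np.testing.assert_allclose(te.samples.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(te.samples.std(axis=0), 1.0, atol=1e-10)

    def test_parameters_come_only_from_train(self, samples12):
        import decnef.decoder as dd

        half = samples12.n_trials // 2
        train = dd._subset(samples12, np.arange(samples12.n_trials) < half)
        test = dd._subset(samples12, np.arange(samples12.n_trials) >= half)
        _, te1 = dn.normalize_train_test(train, test)
        perturbed = dd._subset(samples12, np.arange(samples12.n_trials) >= half)
        perturbed.samples = perturbed.samples + 100.0
        _, te2 = dn.normalize_train_test(train, perturbed)
        expected = np.broadcast_to(100.0 / train.samples.std(axis=0), te1.samples.shape)
        np.testing.assert_allclose(te2.samples - te1.samples, expected, atol=1e-8)

    def test_zero_variance_training_voxel_is_an_error(self, samples12):
        import copy
        import decnef.decoder as dd

        bad = dd._subset(samples12, np.ones(samples12.n_trials, dtype=bool))
        bad.samples = bad.samples.copy()
        bad.samples[:, 3] = 2.5
        with pytest.raises(ValueError, match=r"\[3\]"):
            dn.normalize_train_test(bad, samples12)


class TestPipelineContract:
    def test_out_of_order_stages_are_rejected(self):
        run = make_run(np.random.default_rng(8).normal(size=(2, 60)))
        z = dn.zscore_offline(run)
        with pytest.raises(ValueError, match="must precede"):
            dn.detrend_linear(z)
        d = dn.detrend_linear(run)
        with pytest.raises(ValueError, match="must precede"):
            dn.shift_hemodynamic(d, 4.0)

    def test_stage_cannot_be_applied_twice(self):
        run = make_run(np.zeros((1, 60)))
        once = dn.discard_initial(run, 10.0)
        with pytest.raises(ValueError, match="already applied"):
            dn.discard_initial(once, 10.0)

    def test_sample_counts_equal_total_scheduled_trials(self, session12):
        runs, table = session12
        sm = dn.extract_session(runs, period="rating", mode="offline")
        assert sm.n_trials == len(table[table["period"] == "rating"])

    def test_noiseless_full_roundtrip_recovers_patterns(self, noiseless_session):
        """With zero voxel noise the raw chain reproduces embedded patterns to 1e-10."""
        gt, runs, _ = noiseless_session
        sm = dn.extract_session(runs, period="rating", mode="raw")
        roi = sm.select_voxels(gt.target_indices)
        from decnef.decoder import linearize_rating

        lin = linearize_rating(sm.ratings)
        deltas = lin - lin.mean()
        np.testing.assert_allclose(roi.samples, np.outer(deltas, gt.encode_pattern_unit), atol=1e-10)
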
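"""GLM design construction, OLS identities, and ROI block means."""

import numpy as np
import pandas as pd
import pytest

import nirsblock as nb
from nirsblock.containers import RecordingBundle
from nirsblock.glm import (GlmSpec, build_design_matrix, baseline_normalize,
                           fit_glm, roi_block_means)


@pytest.fixture(scope="module")
def timestamps():
    return np.arange(int(660 * 7.81)) / 7.81


class TestDesignMatrix:
    def test_basis_centres_count(self):
        assert GlmSpec().basis_centers.size == 41
        np.testing.assert_allclose(GlmSpec().basis_centers[[0, -1]], [-5, 35])

    def test_polynomial_mode_column_count(self, schedule, timestamps):
        spec = GlmSpec(drift_basis="poly", drift_order=3)
        d = build_design_matrix(schedule, spec, timestamps)
        assert d.X.shape[1] == 2 * 41 + 4
        assert d.n_task_columns == 82

    def test_cosine_mode_column_count(self, schedule, timestamps):
        d = build_design_matrix(schedule, GlmSpec(), timestamps)
        span = timestamps[-1] - timestamps[0]
        n_cos = int(np.ceil(2 * span * 0.01))
        assert d.X.shape[1] == 82 + 1 + n_cos

    def test_single_event_regressor_peaks_at_shifted_onset(self, timestamps):
        sched = nb.EventSchedule.from_rows([(100.0, 30.0, "wFC")])
        spec = GlmSpec()
        d = build_design_matrix(sched, spec, timestamps)
        for centre in (-5.0, 0.0, 20.0):
            col = d.X[:, [i for i, c in enumerate(d.columns)
                          if c == ("task", "wFC", centre)][0]]
            assert timestamps[np.argmax(col)] == pytest.approx(100 + centre,
                                                               abs=0.2)

    def test_regressor_values_match_gaussian_sum(self, schedule, timestamps):
        d = build_design_matrix(schedule, GlmSpec(), timestamps)
        onsets = [e.onset for e in schedule.of_condition("wFC")]
        centre = 12.0
        col_idx = [i for i, c in enumerate(d.columns)
                   if c == ("task", "wFC", centre)][0]
        for t_i in (100, 800, 2600):
            t = timestamps[t_i]
            want = sum(np.exp(-0.5 * (t - o - centre) ** 2) for o in onsets)
            assert d.X[t_i, col_idx] == pytest.approx(want, abs=1e-12)

    def test_overlapping_condition_blocks_rejected_upstream(self):
        """Two conditions cannot share identical onsets: the schedule itself
        forbids overlapping blocks, so the degenerate design never forms."""
        with pytest.raises(nb.ValidationError, match="overlap"):
            nb.EventSchedule.from_rows(
                [(50.0, 30.0, "wFC"), (50.0, 30.0, "woFC")])

    def test_underdetermined_design_rejected_with_rank_report(self):
        sched = nb.EventSchedule.from_rows([(2.0, 3.0, "wFC")])
        t = np.arange(50) / 7.81   # fewer samples than columns
        with pytest.raises(nb.ValidationError, match="rank"):
            build_design_matrix(sched, GlmSpec(), t)


class TestFit:
    def make_conc(self, montage, data, fs=7.81):
        n = data.shape[0]
        return RecordingBundle(timestamps=np.arange(n) / fs, data=data,
                               state="concentration",
                               component_labels=("HbO", "HbR"),
                               montage=montage, sample_rate=fs)

    def test_exact_ols_recovery(self, montage, schedule, timestamps):
        d = build_design_matrix(schedule, GlmSpec(), timestamps)
        rng = np.random.default_rng(0)
        beta = rng.normal(0, 2, (d.X.shape[1], 30, 2))
        y = np.einsum("tk,kcj->tcj", d.X, beta)
        est = fit_glm(self.make_conc(montage, y), d)
        got = np.moveaxis(est.betas, -1, 0)
        np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_residual_orthogonality(self, montage, schedule, timestamps):
        d = build_design_matrix(schedule, GlmSpec(), timestamps)
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, (timestamps.size, 30, 2))
        est = fit_glm(self.make_conc(montage, y), d)
        beta = np.moveaxis(est.betas, -1, 0).reshape(d.X.shape[1], -1)
        resid = y.reshape(timestamps.size, -1) - d.X @ beta
        assert np.abs(d.X.T @ resid).max() < 1e-8

    def test_zero_data_zero_curves(self, montage, schedule, timestamps):
        d = build_design_matrix(schedule, GlmSpec(), timestamps)
        est = fit_glm(self.make_conc(
            montage, np.zeros((timestamps.size, 30, 2))), d)
        np.testing.assert_allclose(est.curves, 0.0, atol=1e-12)

    def test_nonfinite_channel_reported(self, montage, schedule, timestamps):
        d = build_design_matrix(schedule, GlmSpec(), timestamps)
        y = np.zeros((timestamps.size, 30, 2))
        y[5, 3, 0] = np.nan
        with pytest.raises(nb.ValidationError, match="S2-D3"):
            fit_glm(self.make_conc(montage, y), d)

    def test_baseline_normalization_idempotent(self, noiseless_analysis):
        est = noiseless_analysis.estimate
        again = baseline_normalize(est.curves, est.time_axis,
                                   est.spec.baseline_window)
        np.testing.assert_allclose(again, est.curves, atol=1e-12)
        sel = (est.time_axis >= -5) & (est.time_axis < 0)
        base = est.curves[..., sel].mean(axis=-1)
        np.testing.assert_allclose(base, 0.0, atol=1e-9)

    def test_curve_error_shrinks_with_trial_count(self, montage):
        """White-noise curve RMSE should shrink roughly as 1/sqrt(trials)."""
        fs = 7.81
        rng = np.random.default_rng(4)
        rmses = []
        for n_trials in (5, 20):
            rows, t0 = [(0.0, 30.0, "rest")], 30.0
            for _ in range(n_trials):
                rows.append((t0, 30.0, "wFC")); t0 += 30.0
                rows.append((t0, 30.0, "rest")); t0 += 30.0
            sched = nb.EventSchedule.from_rows(rows)
            t = np.arange(int(t0 * fs)) / fs
            spec = GlmSpec()
            d = build_design_matrix(sched, spec, t)
            beta_true = np.zeros((d.X.shape[1], 30, 2))
            task = d.task_slice("wFC")
            beta_true[task] = 1.0
            y = np.einsum("tk,kcj->tcj", d.X, beta_true)
            y += rng.normal(0, 5.0, y.shape)
            est = fit_glm(self.make_conc(montage, y), d)
            truth = fit_glm(self.make_conc(
                montage, np.einsum("tk,kcj->tcj", d.X, beta_true)), d)
            rmses.append(np.sqrt(np.mean(
                (est.curves - truth.curves) ** 2)))
        ratio = rmses[1] / rmses[0]
        assert ratio == pytest.approx(0.5, abs=0.2)

    def test_matches_classical_block_average(self, montage):
        """Intercept-only GLM on a single condition reproduces the classical
        epoch average on noiseless synthetic data (correlation > 0.99)."""
        fs = 7.81
        rows, t0 = [(0.0, 60.0, "rest")], 60.0
        for _ in range(5):
            rows.append((t0, 30.0, "wFC")); t0 += 30.0
            rows.append((t0, 60.0, "rest")); t0 += 60.0
        sched = nb.EventSchedule.from_rows(rows)
        amp = nb.default_amplitudes(40.0)
        truth = nb.SimulationTruth(amp_hbo=amp, noise=nb.NoiseSpec.silent(),
                                   motion=nb.MotionSpec.none(),
                                   subject_gain_sd=0.0, seed=2)
        rec = nb.simulate_recording(montage, sched, truth, duration_s=t0)
        conc_true = rec.meta["truth"]["conc"]
        bundle = self.make_conc(montage, conc_true)
        spec = GlmSpec(drift_basis="poly", drift_order=0)
        d = build_design_matrix(sched, spec, bundle.timestamps)
        est = fit_glm(bundle, d)
        # classical average of epochs around each onset
        onsets = [e.onset for e in sched.of_condition("wFC")]
        tau = est.time_axis
        epochs = []
        for o in onsets:
            i0 = int(round((o + tau[0]) * fs))
            epochs.append(conc_true[i0:i0 + tau.size, 0, 0])
        avg = np.mean(epochs, axis=0)
        avg -= avg[(tau >= -5) & (tau < 0)].mean()
        curve = est.curves[0, 0, 0]
        corr = np.corrcoef(curve, avg)[0, 1]
        assert corr > 0.99


class TestRoiBlockMeans:
    def test_constant_curve_recovered(self, noiseless_analysis):
        est = noiseless_analysis.estimate
        stats = roi_block_means(est)
        assert set(stats.mean_hbo.index) == set(nb.ROIS)
        assert stats.missing == ()
        assert sum(stats.n_channels_used.values()) == 30

    def test_channel_average_is_arithmetic_mean(self, montage, schedule):
        """Two channels in one ROI with window means a and b give (a+b)/2."""
        truth = nb.SimulationTruth(amp_hbo=nb.default_amplitudes(40.0),
                                   noise=nb.NoiseSpec.silent(),
                                   motion=nb.MotionSpec.none(),
                                   subject_gain_sd=0.0, seed=0)
        rec = nb.simulate_recording(montage, schedule, truth)
        ana = nb.analyze_subject(rec, schedule)
        est = ana.estimate
        ids = montage.channel_ids
        roi = "lPMC"
        ch = [ids.index(c) for c in montage.roi_channels(roi)]
        sel = (est.time_axis >= 10) & (est.time_axis <= 35)
        manual = est.curves[ch][:, 0, 0, sel].mean()
        table = roi_block_means(est).mean_hbo.loc[roi, est.conditions[0]]
        assert table == pytest.approx(manual, abs=1e-9)

    def test_fully_pruned_roi_flagged_missing(self, montage, schedule):
        truth = nb.SimulationTruth(seed=6)
        rec = nb.simulate_recording(montage, schedule, truth)
        for cid in montage.roi_channels("lPFC"):
            rec.data[:, montage.channel_index(cid), :] = 1e-9
        ana = nb.analyze_subject(rec, schedule)
        stats = ana.roi_stats
        assert "lPFC" in stats.missing
        assert np.isnan(stats.mean_hbo.loc["lPFC"]).all()
        assert stats.n_channels_used["lPFC"] == 0
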
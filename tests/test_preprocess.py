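"""Signal-chain unit tests: OD conversion, pruning, wavelet motion
correction, band-pass contract, Beer-Lambert inversion, and commutation."""

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

import nirsblock as nb
from nirsblock.containers import RecordingBundle
from nirsblock.preprocess import (MbllParams, PruneCriteria, bandpass,
                                  intensity_to_od, od_to_concentration,
                                  prune_channels, wavelet_motion_correct)


def make_bundle(montage, data, state="intensity", fs=7.81,
                labels=(760.0, 850.0)):
    n = data.shape[0]
    return RecordingBundle(timestamps=np.arange(n) / fs, data=data,
                           state=state, component_labels=labels,
                           montage=montage, sample_rate=fs)


class TestIntensityToOd:
    def test_constant_channel_gives_zero_od(self, montage):
        rec = make_bundle(montage, np.full((50, 30, 2), 3.7))
        od = intensity_to_od(rec)
        np.testing.assert_allclose(od.data, 0.0, atol=1e-15)

    def test_analytic_point_value(self, montage):
        """A sample at mean/e maps to OD exactly 1 (natural log)."""
        data = np.ones((101, 30, 2))
        # choose a two-point profile whose mean is 1: {1/e, 2 - 1/e}
        data[0] = 1 / np.e
        data[1] = 2 - 1 / np.e
        rec = make_bundle(montage, data)
        od = intensity_to_od(rec)
        assert od.data[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_oracle(self, montage):
        rng = np.random.default_rng(7)
        data = rng.uniform(0.5, 2.0, (200, 30, 2))
        od = intensity_to_od(make_bundle(montage, data))
        # independently coded oracle, scalar loop
        for ci in (0, 17, 29):
            for wi in (0, 1):
                trace = data[:, ci, wi]
                ref = trace.mean()
                want = np.array([-np.log(v / ref) for v in trace])
                np.testing.assert_allclose(od.data[:, ci, wi], want,
                                           atol=1e-12)

    def test_nonpositive_sample_identified(self, montage):
        data = np.ones((50, 30, 2))
        data[10, 4, 1] = 0.0
        with pytest.raises(nb.ValidationError,
                           match=r"sample 10.*S2-D4|S2-D4.*sample 10"):
            intensity_to_od(make_bundle(montage, data))


class TestPruning:
    def test_weak_saturated_and_unstable_reasons(self, montage):
        rng = np.random.default_rng(0)
        data = np.ones((500, 30, 2)) + rng.normal(0, 1e-4, (500, 30, 2))
        data[:, 2, :] = 1e-9                       # weak
        data[:, 5, :] = 1e9                        # saturated
        data[:, 9, :] = 1.0 + rng.normal(0, 0.5, (500, 2))  # unstable
        data = np.abs(data) + 1e-12
        rec = make_bundle(montage, data)
        out = prune_channels(rec, PruneCriteria(max_sd_ratio=0.2))
        ids = montage.channel_ids
        assert out.pruned_channels[ids[2]] == "weak"
        assert out.pruned_channels[ids[5]] == "saturated"
        assert out.pruned_channels[ids[9]] == "high_sd"
        assert len(out.pruned_channels) == 3

    def test_compliant_recording_untouched(self, noisy_recording):
        out = prune_channels(noisy_recording)
        assert out.pruned_channels == {}

    def test_all_pruned_is_fatal(self, montage):
        rec = make_bundle(montage, np.full((50, 30, 2), 1e-9))
        with pytest.raises(nb.ValidationError, match="all channels"):
            prune_channels(rec)


class TestWaveletMotionCorrection:
    def test_smooth_oscillation_preserved(self, montage):
        t = np.arange(2000) / 7.81
        sine = 0.01 * np.sin(2 * np.pi * 0.05 * t)
        data = np.tile(sine[:, None, None], (1, 30, 2))
        rec = make_bundle(montage, data, state="optical_density")
        out = wavelet_motion_correct(rec)
        rms_change = np.sqrt(np.mean((out.data - data) ** 2))
        assert rms_change < 0.05 * np.sqrt(np.mean(data ** 2))
        assert out.n_times == rec.n_times

    def test_spike_suppressed_signal_intact(self, montage):
        rng = np.random.default_rng(3)
        t = np.arange(3000) / 7.81
        base = 0.01 * np.sin(2 * np.pi * 0.03 * t) \
            + rng.normal(0, 0.001, t.size)
        spike_idx = 1500
        spike_amp = 10 * base.std()
        data = np.tile(base[:, None, None], (1, 30, 2))
        data[spike_idx, :, :] += spike_amp
        rec = make_bundle(montage, data, state="optical_density")
        out = wavelet_motion_correct(rec)
        clean = np.tile(base[:, None, None], (1, 30, 2))
        resid_spike = abs(out.data[spike_idx, 0, 0] - clean[spike_idx, 0, 0])
        assert resid_spike <= 0.5 * spike_amp
        off = np.ones(t.size, bool)
        off[spike_idx - 8:spike_idx + 8] = False
        rms_off = np.sqrt(np.mean((out.data[off, 0, 0] - clean[off, 0, 0]) ** 2))
        assert rms_off < 0.1 * np.sqrt(np.mean(clean[off, 0, 0] ** 2))

    def test_zero_trace_maps_to_zero(self, montage):
        rec = make_bundle(montage, np.zeros((512, 30, 2)),
                          state="optical_density")
        out = wavelet_motion_correct(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_too_short_trace_rejected(self, montage):
        rec = make_bundle(montage, np.zeros((5, 30, 2)),
                          state="optical_density")
        with pytest.raises(nb.ValidationError, match="short"):
            wavelet_motion_correct(rec)


class TestBandpass:
    def make_tone(self, montage, freq, n=6000):
        t = np.arange(n) / 7.81
        tone = np.sin(2 * np.pi * freq * t)
        data = np.tile(tone[:, None, None], (1, 30, 2))
        return make_bundle(montage, data, state="optical_density"), t

    def test_passband_gain_near_unity(self, montage):
        rec, t = self.make_tone(montage, 0.05)
        out = bandpass(rec)
        mid = slice(2000, 4000)
        gain = np.abs(out.data[mid, 0, 0]).max()
        assert 0.95 <= gain <= 1.05

    def test_cardiac_band_rejected(self, montage):
        rec, t = self.make_tone(montage, 1.1)
        out = bandpass(rec)
        assert np.abs(out.data[2000:4000, 0, 0]).max() <= 0.05

    def test_dc_removed(self, montage):
        rec = make_bundle(montage, np.full((4000, 30, 2), 0.7),
                          state="optical_density")
        out = bandpass(rec)
        assert np.abs(out.data.mean()) < 1e-6

    def test_invalid_band_rejected(self, montage):
        rec = make_bundle(montage, np.zeros((100, 30, 2)),
                          state="optical_density")
        with pytest.raises(nb.ValidationError, match="Nyquist|band"):
            bandpass(rec, 0.1, 5.0)


class TestMbll:
    def test_zero_od_zero_concentration(self, montage):
        rec = make_bundle(montage, np.zeros((50, 30, 2)),
                          state="optical_density")
        conc = od_to_concentration(rec)
        np.testing.assert_allclose(conc.data, 0.0, atol=1e-15)
        assert conc.component_labels == ("HbO", "HbR")

    def test_forward_map_inverted_exactly(self, montage):
        p = MbllParams()
        truth = np.array([10.0, -3.0])  # uM*mm
        od_pair = p.extinction @ truth
        data = np.tile(od_pair[None, None, :], (50, 30, 1))
        conc = od_to_concentration(
            make_bundle(montage, data, state="optical_density"), p)
        np.testing.assert_allclose(conc.data[:, :, 0], 10.0, atol=1e-9)
        np.testing.assert_allclose(conc.data[:, :, 1], -3.0, atol=1e-9)

    def test_matches_per_sample_solve_oracle(self, montage):
        rng = np.random.default_rng(11)
        data = rng.normal(0, 0.01, (100, 30, 2))
        p = MbllParams()
        conc = od_to_concentration(
            make_bundle(montage, data, state="optical_density"), p)
        for t_i in (0, 42, 99):
            for c_i in (0, 15, 29):
                want = np.linalg.solve(p.extinction, data[t_i, c_i])
                np.testing.assert_allclose(conc.data[t_i, c_i], want,
                                           atol=1e-10)

    def test_singular_extinction_rejected(self):
        with pytest.raises(nb.ValidationError, match="singular"):
            MbllParams(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))

    def test_bandpass_and_mbll_commute(self, montage):
        """Both operations are linear in OD, so their order is irrelevant."""
        rng = np.random.default_rng(2)
        data = rng.normal(0, 0.01, (2000, 30, 2))
        od = make_bundle(montage, data, state="optical_density")
        path_a = od_to_concentration(bandpass(od)).data
        conc = od_to_concentration(od)
        sos = butter(3, [0.01, 0.1], btype="bandpass", fs=7.81, output="sos")
        path_b = sosfiltfilt(sos, conc.data, axis=0)
        np.testing.assert_allclose(path_a, path_b, atol=1e-9)


class TestStateMachine:
    def test_stage_order_enforced(self, montage, noisy_recording):
        with pytest.raises(nb.StateError):
            od_to_concentration(noisy_recording)       # still intensity
        od = intensity_to_od(noisy_recording)
        with pytest.raises(nb.StateError):
            intensity_to_od(od)

    def test_pruned_channels_survive_pipeline(self, montage, schedule):
        truth = nb.SimulationTruth(seed=8)
        rec = nb.simulate_recording(montage, schedule, truth)
        rec.data[:, 7, :] = 1e-9  # kill one channel
        conc = nb.run_pipeline(rec)
        assert montage.channel_ids[7] in conc.pruned_channels
        assert conc.state == "concentration"
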
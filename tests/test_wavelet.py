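import numpy as np
import pytest

from lognstim import core, detect, synth, wavelet


@pytest.fixture(scope="module")
def cfg():
    return wavelet.WaveletConfig()


def noise_trace(seed, duration=60.0, fs=512.0, sd=1.0):
    rng = np.random.default_rng(seed)
    return core.SignalTrace(rng.normal(0, sd, int(duration * fs)), fs=fs)


class TestBandToLevels:
    @pytest.mark.parametrize("fs, lo, hi, expected", [
        (512.0, 1.0, 4.0, {7, 8}),     # D7: 2-4 Hz, D8: 1-2 Hz
        (512.0, 10.0, 40.0, {4, 5}),   # D4: 16-32, D5: 8-16 (75% overlap)
        (512.0, 128.0, 256.0, {1}),    # D1 band by definition
    ])
    def test_dyadic_band_table(self, fs, lo, hi, expected):
        assert wavelet.band_to_levels(fs, lo, hi) == expected

    def test_never_empty_falls_back_to_max_overlap(self):
        # a sliver band overlapping no level by 50% still maps somewhere
        levels = wavelet.band_to_levels(512.0, 31.0, 33.0)
        assert levels

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            wavelet.band_to_levels(512.0, 40.0, 10.0)
        with pytest.raises(ValueError):
            wavelet.band_to_levels(512.0, 1.0, 300.0)


class TestMraComponent:
    def test_perfect_reconstruction(self, cfg):
        trace = noise_trace(0, duration=30.0)
        comps = wavelet.mra_levels(trace, cfg, level=8)
        recon = np.sum(comps, axis=0)
        rel = np.max(np.abs(recon - trace.samples)) / np.max(np.abs(trace.samples))
        assert rel <= 1e-6

    def test_in_band_tone_captured(self, cfg):
        fs = 512.0
        t = np.arange(int(fs * 30)) / fs
        trace = core.SignalTrace(np.sin(2 * np.pi * 20 * t), fs=fs)
        comp = wavelet.mra_component(trace, cfg, band="ictal")
        assert comp.samples.var() / trace.samples.var() >= 0.70

    def test_out_of_band_tone_rejected(self, cfg):
        fs = 512.0
        t = np.arange(int(fs * 30)) / fs
        trace = core.SignalTrace(np.sin(2 * np.pi * 1.5 * t), fs=fs)
        comp = wavelet.mra_component(trace, cfg, band="ictal")
        assert comp.samples.var() / trace.samples.var() < 0.10

    def test_trace_shorter_than_filter_support_rejected(self, cfg):
        trace = core.SignalTrace(np.ones(4), fs=512.0)
        with pytest.raises(ValueError, match="filter support"):
            wavelet.mra_component(trace, cfg)


class TestFitBaseline:
    def test_moments_of_gaussian_component(self, cfg):
        trace = noise_trace(1, duration=120.0)
        comp = wavelet.mra_component(trace, cfg, band="ictal")
        base = wavelet.fit_baseline(comp, (0.0, 120.0))
        assert base.mu_b == pytest.approx(0.0, abs=0.03 * comp.samples.std())
        assert base.sigma_b == pytest.approx(comp.samples.std(), rel=0.03)

    def test_constant_component_triggers_downstream_error(self, cfg):
        comp = core.SignalTrace(np.full(512 * 20, 2.0), fs=512.0)
        base = wavelet.fit_baseline(comp, (0.0, 20.0))
        assert base.sigma_b == 0.0
        with pytest.raises(ValueError):
            wavelet.detect_ictal(comp, base, cfg)

    def test_window_containing_burst_inflates_sigma(self, cfg):
        params = synth.SynthesisParams(duration=120.0, seed=3, fs=512.0)
        truth = synth.GroundTruth(
            fast_events=core.EventTrain(times=np.empty(0), source="synthetic"),
            slow_events=core.EventTrain(times=np.empty(0), source="synthetic"),
            ictal=core.IctalLabelSet(windows=[(70.0, 90.0)], t_tot=120.0))
        traces = synth.render_trace(params, truth)
        comp = wavelet.mra_component(traces["CTX"], cfg, band="ictal")
        clean = wavelet.fit_baseline(comp, (0.0, 60.0))
        dirty = wavelet.fit_baseline(comp, (60.0, 120.0))
        assert dirty.sigma_b >= 2.0 * clean.sigma_b

    def test_window_bounds_checked(self, cfg):
        comp = noise_trace(4, duration=30.0)
        with pytest.raises(ValueError):
            wavelet.fit_baseline(comp, (10.0, 50.0))
        with pytest.raises(ValueError):
            wavelet.fit_baseline(comp, (0.0, 5.0))


class TestDetectIctal:
    def make_labelled_recording(self, seed, windows, duration):
        params = synth.SynthesisParams(duration=duration, seed=seed, fs=512.0)
        truth = synth.GroundTruth(
            fast_events=core.EventTrain(times=np.empty(0), source="synthetic"),
            slow_events=core.EventTrain(times=np.empty(0), source="synthetic"),
            ictal=core.IctalLabelSet(windows=windows, t_tot=duration))
        return synth.render_trace(params, truth)["CTX"], truth

    def test_recovers_truth_windows(self, cfg):
        windows = [(60.0, 90.0), (180.0, 220.0), (300.0, 330.0)]
        trace, truth = self.make_labelled_recording(5, windows, 360.0)
        comp = wavelet.mra_component(trace, cfg, band="ictal")
        base = wavelet.fit_baseline(comp, (0.0, 50.0))
        labels = wavelet.detect_ictal(comp, base, cfg)
        assert len(labels) == 3
        for (on, off), (ton, toff) in zip(labels.windows, windows):
            assert on == pytest.approx(ton, abs=1.0)
            assert off == pytest.approx(toff, abs=1.0)

    def test_no_false_positives_on_baseline_noise(self, cfg):
        # Gaussian 5-sigma exceedance ~ 5.7e-7/sample: 0 labels in 10 min
        trace = noise_trace(6, duration=600.0)
        comp = wavelet.mra_component(trace, cfg, band="ictal")
        base = wavelet.fit_baseline(comp, (0.0, 60.0))
        labels = wavelet.detect_ictal(comp, base, cfg)
        assert len(labels) == 0

    def test_close_windows_merge_with_cluster_gap(self, cfg):
        fs = 512.0
        t = np.arange(int(fs * 60)) / fs
        x = np.random.default_rng(7).normal(0, 1.0, t.size)
        burst = 40.0 * np.sin(2 * np.pi * 20 * t)
        for a, b in [(20.0, 25.0), (26.0, 31.0)]:  # 1 s apart < 2 s gap
            sel = (t >= a) & (t < b)
            x[sel] += burst[sel]
        comp = wavelet.mra_component(core.SignalTrace(x, fs=fs), cfg, "ictal")
        base = wavelet.fit_baseline(comp, (0.0, 15.0))
        labels = wavelet.detect_ictal(comp, base, cfg)
        assert len(labels) == 1

    def test_offset_invariance(self, cfg):
        trace, _ = self.make_labelled_recording(8, [(30.0, 50.0)], 120.0)
        shifted = core.SignalTrace(trace.samples + 500.0, fs=trace.fs)
        for tr in (trace, shifted):
            comp = wavelet.mra_component(tr, cfg, band="ictal")
            base = wavelet.fit_baseline(comp, (0.0, 25.0))
            labels = wavelet.detect_ictal(comp, base, cfg)
            assert len(labels) == 1


class TestPictal:
    def test_stim_mode_uses_protocol_duration(self):
        labels = core.IctalLabelSet(windows=[(0.0, 10.0), (30.0, 40.0)],
                                    t_tot=100.0, mode="stim")
        assert wavelet.compute_pictal(labels) == pytest.approx(20.0)

    def test_ctrl_mode_spans_first_onset_to_last_offset(self):
        labels = core.IctalLabelSet(windows=[(0.0, 10.0), (30.0, 40.0)],
                                    t_tot=100.0, mode="ctrl")
        assert wavelet.compute_pictal(labels) == pytest.approx(50.0)

    def test_stim_mode_zero_without_labels_ctrl_errors(self):
        stim = core.IctalLabelSet(windows=[], t_tot=100.0, mode="stim")
        assert wavelet.compute_pictal(stim) == 0.0
        ctrl = core.IctalLabelSet(windows=[], t_tot=100.0, mode="ctrl")
        with pytest.raises(ValueError, match="t_TOT undefined"):
            wavelet.compute_pictal(ctrl)

    def test_detected_pictal_tracks_generator_duty_cycle(self, cfg):
        # 15 bursts of 18 s every 120 s -> 15% duty cycle over 30 min
        duration = 1800.0
        windows = [(60.0 + 120.0 * k, 78.0 + 120.0 * k) for k in range(15)]
        params = synth.SynthesisParams(duration=duration, seed=9, fs=512.0)
        truth = synth.GroundTruth(
            fast_events=core.EventTrain(times=np.empty(0), source="synthetic"),
            slow_events=core.EventTrain(times=np.empty(0), source="synthetic"),
            ictal=core.IctalLabelSet(windows=windows, t_tot=duration))
        trace = synth.render_trace(params, truth)["CTX"]
        comp = wavelet.mra_component(trace, cfg, band="ictal")
        base = wavelet.fit_baseline(comp, (0.0, 50.0))
        labels = wavelet.detect_ictal(comp, base, cfg, mode="stim")
        detected = wavelet.compute_pictal(labels)
        true_duty = 100.0 * truth.ictal.total_duration() / duration
        assert detected == pytest.approx(true_duty, abs=2.0)


class TestIctalAmplitude:
    def test_sinusoid_peak_to_peak(self):
        fs = 512.0
        t = np.arange(int(fs * 20)) / fs
        trace = core.SignalTrace(120.0 * np.sin(2 * np.pi * 5 * t), fs=fs)
        labels = core.IctalLabelSet(windows=[(2.0, 8.0)], t_tot=20.0)
        amp = wavelet.ictal_amplitude([trace], labels)
        assert amp == pytest.approx(240.0, rel=0.01)

    def test_constant_trace_is_zero(self):
        trace = core.SignalTrace(np.full(5120, 4.0), fs=512.0)
        labels = core.IctalLabelSet(windows=[(1.0, 5.0)], t_tot=10.0)
        assert wavelet.ictal_amplitude([trace], labels) == 0.0

    def test_empty_labels_rejected(self):
        trace = core.SignalTrace(np.ones(512), fs=512.0)
        with pytest.raises(ValueError):
            wavelet.ictal_amplitude([trace],
                                    core.IctalLabelSet(windows=[], t_tot=1.0))

    def test_matches_generator_envelope(self):
        params = synth.SynthesisParams(duration=60.0, seed=10, fs=512.0,
                                       noise_sd=1.0, ictal_amp=400.0)
        truth = synth.GroundTruth(
            fast_events=core.EventTrain(times=np.empty(0), source="synthetic"),
            slow_events=core.EventTrain(times=np.empty(0), source="synthetic"),
            ictal=core.IctalLabelSet(windows=[(20.0, 40.0)], t_tot=60.0))
        traces = synth.render_trace(params, truth)
        amp = wavelet.ictal_amplitude([traces["CTX"]], truth.ictal)
        assert amp == pytest.approx(2 * 400.0, rel=0.05)
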
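"""Filtering, resampling, channel selection and epoching."""

import numpy as np
import pytest
from scipy import signal

import ssvep_tffnet as st
from ssvep_tffnet.preprocessing import round_half_away


def _recording(data, fs, events=(), names=None):
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return st.RawRecording(data=data, fs=fs, channel_names=names,
                          events=list(events), subject_id=0)


class TestBandpass:
    def test_dc_rejected(self):
        rec = _recording(np.full((2, 2560), 5.0), 256.0)
        out = st.bandpass_filter(rec, st.PreprocessConfig(band_low=6, band_high=80,
                                                          target_fs=256))
        assert np.abs(out.data).max() <= 1e-6 * 5.0

    def test_passband_gain_matches_squared_butterworth_response(self):
        # forward-backward filtering applies |H|^2; at 10 Hz inside 6-80 Hz
        # the squared fourth-order response is essentially unity
        fs = 256.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        cfg = st.PreprocessConfig(band_low=6, band_high=80, target_fs=fs)
        out = st.bandpass_filter(_recording(x, fs), cfg)
        edge = int(0.5 * fs)
        peak = np.abs(out.data[0, edge:-edge]).max()
        sos = signal.butter(4, [6, 80], btype="bandpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[10.0], fs=fs)
        expected = np.abs(h[0]) ** 2
        assert peak == pytest.approx(expected, rel=0.01)
        assert peak == pytest.approx(1.0, rel=0.01)

    def test_zero_phase_symmetry(self):
        # a symmetric pulse stays symmetric about its centre
        fs = 256.0
        n = 1024
        t = (np.arange(n) - (n - 1) / 2) / fs   # symmetric about the centre
        pulse = np.exp(-(t ** 2) / (2 * 0.05 ** 2))[None, :]
        out = st.bandpass_filter(_recording(pulse, fs),
                                 st.PreprocessConfig(band_low=6, band_high=80, target_fs=fs))
        y = out.data[0]
        asym = np.abs(y - y[::-1]).max() / np.abs(y).max()
        assert asym < 1e-8

    def test_band_edge_at_nyquist_rejected(self):
        rec = _recording(np.zeros((1, 256)), 256.0)
        with pytest.raises(ValueError, match="Nyquist"):
            st.bandpass_filter(rec, _cfg_unsafe(100.0, 130.0, 256.0))


def _cfg_unsafe(lo, hi, fs):
    """Bypass config validation to exercise the filter's own check."""
    cfg = st.PreprocessConfig(band_low=7, band_high=64, target_fs=1000.0)
    cfg.band_low, cfg.band_high, cfg.target_fs = lo, hi, fs
    return cfg


class TestResample:
    def test_downsample_by_8_rescales_onsets(self):
        events = [st.StimulusEvent(2048, 0, 10.0, 0.0)]
        rec = _recording(np.random.default_rng(0).standard_normal((2, 4096)),
                         2048.0, events)
        out = st.resample(rec, 256.0)
        assert out.fs == 256.0
        assert out.data.shape[1] == 512
        assert out.events[0].onset_sample == 256

    def test_identity(self):
        rec = _recording(np.zeros((1, 100)), 250.0)
        assert st.resample(rec, 250.0) is rec

    def test_upsampling_rejected(self):
        rec = _recording(np.zeros((1, 100)), 250.0)
        with pytest.raises(ValueError, match="upsampling"):
            st.resample(rec, 500.0)

    def test_tone_frequency_preserved(self):
        fs = 1000.0
        t = np.arange(int(fs)) / fs
        rec = _recording(np.sin(2 * np.pi * 10 * t)[None, :], fs)
        out = st.resample(rec, 250.0)
        spec = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(out.data.shape[1], 1 / 250.0)
        assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=0.5)

    def test_idempotent_at_same_rate(self):
        fs = 1000.0
        rec = _recording(np.random.default_rng(1).standard_normal((2, 2000)), fs)
        once = st.resample(rec, 250.0)
        twice = st.resample(once, 250.0)
        assert np.array_equal(once.data, twice.data)


class TestSelectChannels:
    def test_subset_and_order(self):
        data = np.arange(12, dtype=float).reshape(4, 3)
        rec = _recording(data, 256.0, names=["a", "b", "c", "d"])
        out = st.select_channels(rec, ["d", "b"])
        assert out.channel_names == ["d", "b"]
        assert np.array_equal(out.data, data[[3, 1]])

    def test_identity_order(self):
        rec = _recording(np.zeros((2, 10)), 256.0, names=["x", "y"])
        out = st.select_channels(rec, ["x", "y"])
        assert np.array_equal(out.data, rec.data)

    def test_unknown_label_lists_available(self):
        rec = _recording(np.zeros((2, 10)), 256.0, names=["x", "y"])
        with pytest.raises(KeyError, match=r"XX.*x.*y"):
            st.select_channels(rec, ["XX"])


class TestExtractEpochs:
    def test_latency_offset_rounding(self):
        # 0.135 s at 256 Hz -> 34.56 -> 35 samples (half away from zero)
        assert round_half_away(0.135 * 256) == 35
        fs = 256.0
        data = np.zeros((1, 1000))
        data[0, 100 + 35] = 1.0  # marker exactly at expected epoch start
        rec = _recording(data, fs, [st.StimulusEvent(100, 3, 10.0, 0.0)])
        cfg = st.PreprocessConfig(band_low=7, band_high=64, target_fs=fs,
                                  latency_s=0.135, window_s=1.0)
        out = st.extract_epochs(rec, cfg)
        assert out.epochs.shape == (1, 1, 256)
        assert out.epochs[0, 0, 0] == 1.0
        assert out.labels[0] == 3

    def test_counts_match_paradigm(self, small_epochs):
        # 3 subjects x 2 blocks x 12 classes
        assert small_epochs.n_trials == 3 * 2 * 12
        assert small_epochs.epochs.shape[2] == 256
        for cls in range(12):
            assert int((small_epochs.labels == cls).sum()) == 6

    def test_overrunning_trials_dropped_with_warning(self):
        fs = 256.0
        rec = _recording(np.zeros((1, 300)), fs,
                         [st.StimulusEvent(0, 0, 10.0, 0.0),
                          st.StimulusEvent(200, 1, 10.0, 0.0)])
        cfg = st.PreprocessConfig(band_low=7, band_high=64, target_fs=fs,
                                  latency_s=0.0, window_s=1.0)
        with pytest.warns(UserWarning, match="dropped 1"):
            out = st.extract_epochs(rec, cfg)
        assert out.n_trials == 1

    def test_all_dropped_is_error(self):
        rec = _recording(np.zeros((1, 10)), 256.0,
                         [st.StimulusEvent(0, 0, 10.0, 0.0)])
        cfg = st.PreprocessConfig(band_low=7, band_high=64, target_fs=256.0,
                                  latency_s=0.0, window_s=1.0)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no trials"):
                st.extract_epochs(rec, cfg)

    def test_channel_selection_commutes_with_epoching(self, small_sim):
        rec = small_sim.recordings[0]
        cfg = st.PreprocessConfig(band_low=7, band_high=64, target_fs=256.0,
                                  latency_s=0.135, window_s=0.5)
        subset = ["O1", "Oz", "O2"]
        a = st.extract_epochs(st.select_channels(rec, subset), cfg)
        b = st.extract_epochs(rec, cfg)
        sel = [rec.channel_names.index(ch) for ch in subset]
        assert np.array_equal(a.epochs, b.epochs[:, sel, :])


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(band_low=100.0, band_high=130.0, target_fs=256.0),  # above Nyquist
        dict(band_low=64.0, band_high=7.0),                      # inverted
        dict(band_low=7.0, band_high=64.0, window_s=-1.0),
        dict(band_low=7.0, band_high=64.0, filter_order=0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            st.PreprocessConfig(**kwargs)
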
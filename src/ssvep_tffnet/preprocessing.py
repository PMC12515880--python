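"""Recording model and preprocessing for SSVEP decoding.

A :class:`RawRecording` is continuous multichannel EEG (microvolts) with
stimulus events. Preprocessing follows standard offline SSVEP practice:
zero-phase Butterworth band-pass filtering, integer-safe resampling,
channel selection, and latency-corrected epoch extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "StimulusEvent",
    "RawRecording",
    "PreprocessConfig",
    "EpochSet",
    "bandpass_filter",
    "resample",
    "select_channels",
    "extract_epochs",
    "preprocess_recording",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1).

    Used for every seconds-to-samples conversion so that epoch
    boundaries are reproducible across platforms (NumPy/Python round
    half to even by default).
    """
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


@dataclass(frozen=True)
class StimulusEvent:
    onset_sample: int
    class_index: int
    stim_freq: float     # Hz
    stim_phase: float    # radians


@dataclass
class RawRecording:
    """Continuous EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[StimulusEvent]
    subject_id: int | str = 0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PreprocessConfig:
    """Filter band, resampling target, latency and window settings."""

    band_low: float = 7.0
    band_high: float = 64.0
    filter_order: int = 4
    target_fs: float = 250.0
    latency_s: float = 0.13
    window_s: float = 1.0
    channel_subset: list[str] | None = None

    def __post_init__(self):
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= self.target_fs / 2:
            raise ValueError(
                f"band edge {self.band_high} Hz reaches Nyquist of target fs "
                f"{self.target_fs} Hz"
            )
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")


@dataclass
class EpochSet:
    """Stack of fixed-length trials: ``epochs`` is n x C x T."""

    epochs: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    fs: float
    window_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        n = self.epochs.shape[0]
        if not (len(self.labels) == len(self.subjects) == n):
            raise ValueError("epochs, labels and subjects must align")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def subject_ids(self) -> np.ndarray:
        return np.unique(self.subjects)

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.epochs[mask], self.labels[mask], self.subjects[mask],
                        self.fs, self.window_s, self.channel_names)

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        first = parts[0]
        return EpochSet(
            np.concatenate([p.epochs for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subjects for p in parts]),
            first.fs, first.window_s, first.channel_names,
        )


def bandpass_filter(rec: RawRecording, cfg: PreprocessConfig) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth band-pass per channel.

    Events are untouched; the effective magnitude response is the
    squared response of the analog prototype because of the two passes.
    """
    nyq = rec.fs / 2
    if cfg.band_high >= nyq or cfg.band_low >= nyq:
        raise ValueError(
            f"band ({cfg.band_low}-{cfg.band_high} Hz) reaches Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(cfg.filter_order, [cfg.band_low, cfg.band_high],
                        btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def resample(rec: RawRecording, target_fs: float) -> RawRecording:
    """Polyphase downsampling; event onsets are rescaled consistently."""
    if target_fs > rec.fs:
        raise ValueError(f"upsampling {rec.fs} -> {target_fs} Hz is not supported")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    scale = target_fs / rec.fs
    events = [replace(ev, onset_sample=round_half_away(ev.onset_sample * scale))
              for ev in rec.events]
    return replace(rec, data=data, fs=target_fs, events=events)


def select_channels(rec: RawRecording, subset: list[str]) -> RawRecording:
    """Restrict and reorder channels to ``subset`` order."""
    missing = [ch for ch in subset if ch not in rec.channel_names]
    if missing:
        raise KeyError(
            f"unknown channel(s) {missing}; available: {rec.channel_names}"
        )
    idx = [rec.channel_names.index(ch) for ch in subset]
    return replace(rec, data=rec.data[idx], channel_names=list(subset))


def extract_epochs(rec: RawRecording, cfg: PreprocessConfig) -> EpochSet:
    """Cut latency-corrected fixed-length epochs at each stimulus event.

    Each epoch starts ``round(latency_s * fs)`` samples after the event
    onset and spans ``round(window_s * fs)`` samples. Trials whose
    window overruns the recording are dropped with a warning.
    """
    offset = round_half_away(cfg.latency_s * rec.fs)
    T = round_half_away(cfg.window_s * rec.fs)
    epochs, labels = [], []
    n_dropped = 0
    for ev in rec.events:
        start = ev.onset_sample + offset
        stop = start + T
        if start < 0 or stop > rec.n_samples:
            n_dropped += 1
            continue
        epochs.append(rec.data[:, start:stop])
        labels.append(ev.class_index)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} trial(s) whose window overran the recording")
    if not epochs:
        raise ValueError("no trials survived epoching")
    arr = np.stack(epochs)
    subjects = np.full(len(labels), rec.subject_id)
    return EpochSet(arr, np.asarray(labels), subjects, rec.fs, cfg.window_s,
                    list(rec.channel_names))


def preprocess_recording(rec: RawRecording, cfg: PreprocessConfig) -> EpochSet:
    """Full pipeline: band-pass, resample, channel subset, epoch."""
    rec = bandpass_filter(rec, cfg)
    if cfg.target_fs != rec.fs:
        rec = resample(rec, cfg.target_fs)
    if cfg.channel_subset:
        rec = select_channels(rec, cfg.channel_subset)
    return extract_epochs(rec, cfg)
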
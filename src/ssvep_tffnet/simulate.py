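"""Synthetic SSVEP generator.

Produces multichannel recordings that mimic the structure of the public
frequency-tagging paradigms: per-subject blocks of trials (one trial
per stimulus class per block, in random order), stimulus frequencies on
a grid with phases advancing by 0.5 pi per stimulus, occipital channel
layouts, a visual-evoked latency, harmonics, and broadband (pink +
white) background noise at a controlled in-band signal-to-noise ratio.

The signal model per trial is deliberately minimal and fully seeded:

    s_c(t) = gain_c * amp_subj * sum_h a_h * sin(2 pi h f (t - tau) + h phi)

for t >= tau (the evoked latency), plus noise scaled so that the mean
in-band (7-64 Hz) signal-to-noise power ratio across channels equals
``snr_db``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import RawRecording, StimulusEvent, round_half_away

__all__ = [
    "SimConfig",
    "SimDataset",
    "preset_12class",
    "preset_40class",
    "simulate_trial",
    "simulate_dataset",
    "estimate_snr",
]

# Channel layouts mirroring the public paradigms.
_CHANNELS_12CLASS = ["PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2"]
_CHANNELS_40CLASS = ["Pz", "PO3", "PO5", "PO4", "PO6", "POz", "O1", "Oz", "O2"]

SNR_CAP_DB = 300.0  # sentinel for noise-free trials


@dataclass
class SimConfig:
    """All knobs of the generator; defaults mirror the 12-class paradigm."""

    n_subjects: int = 10
    n_classes: int = 12
    freqs: np.ndarray = field(default_factory=lambda: 9.25 + 0.5 * np.arange(12))
    phases: np.ndarray = field(default_factory=lambda: 0.5 * np.pi * np.arange(12))
    fs: float = 256.0
    trial_s: float = 4.0
    n_blocks: int = 15
    snr_db: float = 5.0
    harmonic_amps: tuple[float, ...] = (1.0, 0.4, 0.2)
    n_channels: int = 8
    channel_names: list[str] = field(default_factory=lambda: list(_CHANNELS_12CLASS))
    channel_gains: np.ndarray | None = None
    latency_s: float = 0.135
    subject_amp_sd: float = 0.3
    subject_latency_jitter_s: float = 0.01
    pink_fraction: float = 0.7
    white_fraction: float = 0.3
    gap_s: float = 0.5
    band: tuple[float, float] = (7.0, 64.0)
    seed: int = 0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if len(self.freqs) != self.n_classes or len(self.phases) != self.n_classes:
            raise ValueError("freqs and phases must each have n_classes entries")
        n_harm = len(self.harmonic_amps)
        if float(self.freqs.max()) * n_harm >= self.fs / 2:
            raise ValueError(
                f"highest harmonic {self.freqs.max() * n_harm:.1f} Hz reaches "
                f"Nyquist ({self.fs / 2:.1f} Hz); reduce harmonics or raise fs"
            )
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names must have n_channels entries")
        if self.channel_gains is None:
            # occipital-weighted gains, fixed per layout
            self.channel_gains = 0.7 + 0.6 * np.cos(
                np.linspace(-1.0, 1.0, self.n_channels))
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)


def preset_12class(**overrides) -> SimConfig:
    """12 stimuli, 9.25-14.75 Hz step 0.5, 8 occipital channels, 256 Hz."""
    return SimConfig(**overrides)


def preset_40class(**overrides) -> SimConfig:
    """40 stimuli, 8-15.8 Hz step 0.2, 9 parieto-occipital channels, 250 Hz."""
    defaults = dict(
        n_classes=40,
        freqs=8.0 + 0.2 * np.arange(40),
        phases=np.mod(0.5 * np.pi * np.arange(40), 2 * np.pi),
        fs=250.0,
        n_channels=9,
        channel_names=list(_CHANNELS_40CLASS),
        latency_s=0.13,
        n_blocks=6,
        harmonic_amps=(1.0, 0.4),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class SimDataset:
    recordings: list[RawRecording]
    config: SimConfig


@dataclass
class _SubjectParams:
    amp: float
    latency_s: float


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float) -> np.ndarray:
    """Spectrally shaped noise with power ~ 1/f (unit variance per channel)."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * shaping, n=n, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Channel-mean in-band power via the periodogram (ratio use only)."""
    x = np.atleast_2d(x)
    freqs = np.fft.rfftfreq(x.shape[-1], 1.0 / fs)
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    mask = (freqs >= band[0]) & (freqs < band[1])
    return float(spec[:, mask].sum() / (x.shape[0] * x.shape[1]))


def _noise(rng: np.random.Generator, cfg: SimConfig, n_ch: int, n: int) -> np.ndarray:
    total = cfg.pink_fraction + cfg.white_fraction
    if total <= 0:
        return np.zeros((n_ch, n))
    w_pink = cfg.pink_fraction / total
    w_white = cfg.white_fraction / total
    noise = np.zeros((n_ch, n))
    if w_pink > 0:
        noise += np.sqrt(w_pink) * _pink_noise(rng, n_ch, n, cfg.fs)
    if w_white > 0:
        noise += np.sqrt(w_white) * rng.standard_normal((n_ch, n))
    return noise


def simulate_trial(class_index: int, subject_params: _SubjectParams | None,
                   cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """One trial segment (channels x samples) for a stimulus class.

    The oscillation starts ``latency_s`` after segment onset; harmonic h
    carries phase ``h * phi``. Noise is a pink/white mixture scaled so
    the channel-mean in-band SNR equals ``cfg.snr_db``.
    """
    if not 0 <= class_index < cfg.n_classes:
        raise ValueError(f"class_index {class_index} out of range")
    if subject_params is None:
        subject_params = _SubjectParams(amp=1.0, latency_s=cfg.latency_s)
    rng = rng or np.random.default_rng(cfg.seed)
    n = round_half_away(cfg.trial_s * cfg.fs)
    t = np.arange(n) / cfg.fs
    f = cfg.freqs[class_index]
    phi = cfg.phases[class_index]
    tau = subject_params.latency_s
    wave = np.zeros(n)
    active = t >= tau
    for h, a_h in enumerate(cfg.harmonic_amps, start=1):
        wave[active] += a_h * np.sin(2 * np.pi * h * f * (t[active] - tau) + h * phi)
    sig = cfg.channel_gains[:, None] * subject_params.amp * wave[None, :]
    noise = _noise(rng, cfg, cfg.n_channels, n)
    if np.abs(noise).max() == 0.0:
        return sig
    p_sig = _band_power(sig, cfg.fs, cfg.band)
    p_noise = _band_power(noise, cfg.fs, cfg.band)
    target = p_sig / 10.0 ** (cfg.snr_db / 10.0)
    noise *= np.sqrt(target / p_noise)
    return sig + noise


def _subject_streams(cfg: SimConfig):
    root = np.random.SeedSequence(cfg.seed)
    return root.spawn(cfg.n_subjects)


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Assemble one continuous recording per subject.

    Per subject: amplitude ~ lognormal(0, subject_amp_sd), a latency
    jitter, and ``n_blocks`` blocks each containing all classes once in
    random order, separated by noise-only inter-trial gaps.
    """
    recordings = []
    gap_n = round_half_away(cfg.gap_s * cfg.fs)
    trial_n = round_half_away(cfg.trial_s * cfg.fs)
    for subj, seed_seq in enumerate(_subject_streams(cfg)):
        rng = np.random.default_rng(seed_seq)
        params = _SubjectParams(
            amp=float(np.exp(rng.normal(0.0, cfg.subject_amp_sd))),
            latency_s=cfg.latency_s + float(rng.normal(0.0, cfg.subject_latency_jitter_s)),
        )
        order = np.concatenate([rng.permutation(cfg.n_classes)
                                for _ in range(cfg.n_blocks)])
        segments = []
        events = []
        cursor = 0
        for class_index in order:
            gap = np.sqrt(0.5) * _noise(rng, cfg, cfg.n_channels, gap_n)
            segments.append(gap)
            cursor += gap_n
            trial = simulate_trial(int(class_index), params, cfg, rng)
            events.append(StimulusEvent(
                onset_sample=cursor,
                class_index=int(class_index),
                stim_freq=float(cfg.freqs[class_index]),
                stim_phase=float(cfg.phases[class_index]),
            ))
            segments.append(trial)
            cursor += trial_n
        segments.append(np.sqrt(0.5) * _noise(rng, cfg, cfg.n_channels, gap_n))
        data = np.concatenate(segments, axis=1)
        recordings.append(RawRecording(
            data=data, fs=cfg.fs, channel_names=list(cfg.channel_names),
            events=events, subject_id=subj,
        ))
    return SimDataset(recordings=recordings, config=cfg)


def estimate_snr(trial: np.ndarray, f: float, fs: float,
                 band: tuple[float, float] = (7.0, 64.0),
                 harmonic_amps: tuple[float, ...] = (1.0, 0.4, 0.2),
                 df_signal: float = 0.5) -> float:
    """In-band SNR (dB) of a trial given its stimulus frequency.

    Power within ``df_signal`` Hz of f and its harmonics counts as
    signal; the remaining in-band power counts as noise. Noise-free
    trials return the ``SNR_CAP_DB`` sentinel.
    """
    if not band[0] <= f < band[1]:
        raise ValueError(f"stimulus frequency {f} Hz outside band {band}")
    trial = np.atleast_2d(trial)
    n = trial.shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    power = (np.abs(np.fft.rfft(trial, axis=1)) ** 2).mean(axis=0)
    in_band = (freqs >= band[0]) & (freqs < band[1])
    sig_mask = np.zeros_like(in_band)
    for h in range(1, len(harmonic_amps) + 1):
        sig_mask |= np.abs(freqs - h * f) <= df_signal
    sig_mask &= in_band
    p_sig = power[sig_mask].sum()
    p_noise = power[in_band & ~sig_mask].sum()
    if p_noise <= 1e-9 * p_sig:   # numerically noise-free
        return SNR_CAP_DB
    return float(10.0 * np.log10(max(p_sig, 1e-300) / p_noise))
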
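"""Complex-spectrum features for the frequency branch.

The frequency branch consumes, per channel, the real and imaginary
parts of the DFT over a fixed analysis band (7-64 Hz by default) at a
fixed 0.2 Hz resolution. The fixed resolution is reached by zero-
padding each epoch to N = fs / df samples, so the feature width is
independent of the window length: with the defaults every channel
contributes 285 real + 285 imaginary values, i.e. a C x 570 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralConfig",
    "ComplexSpectrum",
    "band_bins",
    "complex_spectrum",
    "magnitude_spectrum",
    "spectra_for_epochs",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Analysis band [f_lo, f_hi) and DFT resolution.

    The band is half-open so that (f_hi - f_lo) / df bins exactly tile
    it: 7-64 Hz at 0.2 Hz gives 285 bins per part.
    """

    f_lo: float = 7.0
    f_hi: float = 64.0
    df: float = 0.2

    def __post_init__(self):
        if self.df <= 0:
            raise ValueError("df must be positive")
        if not self.f_lo < self.f_hi:
            raise ValueError(f"empty band: [{self.f_lo}, {self.f_hi})")

    @property
    def n_bins(self) -> int:
        b = (self.f_hi - self.f_lo) / self.df
        return int(round(b))


@dataclass
class ComplexSpectrum:
    """C x 2B matrix: per channel, B real parts then B imaginary parts."""

    values: np.ndarray
    bin_freqs: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return len(self.bin_freqs)


def band_bins(fs: float, cfg: SpectralConfig = SpectralConfig()):
    """Transform length and DFT bin indices covering the analysis band.

    Returns ``(N, bin_indices, bin_freqs)`` where ``N = fs / df`` is the
    zero-padded transform length and bin ``k`` sits at ``k * df`` Hz.
    """
    n_float = fs / cfg.df
    N = int(round(n_float))
    if abs(n_float - N) > 1e-9:
        raise ValueError(
            f"df={cfg.df} Hz does not divide fs={fs} Hz into an integer "
            f"transform length; pick df with fs/df integral (e.g. {fs / N:.6g})"
        )
    if cfg.n_bins < 1:
        raise ValueError(f"empty band: [{cfg.f_lo}, {cfg.f_hi}) at df={cfg.df}")
    k_lo = int(np.ceil(cfg.f_lo / cfg.df - 1e-9))
    bins = np.arange(k_lo, k_lo + cfg.n_bins)
    if bins[-1] > N // 2:
        raise ValueError("band exceeds the Nyquist bin of the transform")
    freqs = bins * cfg.df
    return N, bins, freqs


def _dft_band(epoch: np.ndarray, fs: float, cfg: SpectralConfig):
    epoch = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    N, bins, freqs = band_bins(fs, cfg)
    T = epoch.shape[1]
    if T > N:
        raise ValueError(
            f"epoch of {T} samples exceeds transform length {N}; the window "
            f"is longer than the {cfg.df} Hz resolution allows"
        )
    spec = np.fft.rfft(epoch, n=N, axis=1)[:, bins]
    return spec, freqs


def complex_spectrum(epoch: np.ndarray, fs: float,
                     cfg: SpectralConfig = SpectralConfig()) -> ComplexSpectrum:
    """Concatenated real/imaginary DFT parts over the analysis band.

    ``epoch`` is C x T (already band-pass filtered); the output is a
    C x 2B matrix with unscaled DFT values (the network's first
    batch-normalisation stage absorbs overall scale).
    """
    spec, freqs = _dft_band(epoch, fs, cfg)
    values = np.concatenate([spec.real, spec.imag], axis=1)
    return ComplexSpectrum(values=values, bin_freqs=freqs)


def magnitude_spectrum(epoch: np.ndarray, fs: float,
                       cfg: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Per-bin magnitude sqrt(Re^2 + Im^2); C x B matrix."""
    spec, _ = _dft_band(epoch, fs, cfg)
    return np.abs(spec)


def spectra_for_epochs(epochs: np.ndarray, fs: float,
                       cfg: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Vectorised complex spectra for an n x C x T stack -> n x C x 2B."""
    epochs = np.asarray(epochs, dtype=np.float64)
    N, bins, _ = band_bins(fs, cfg)
    if epochs.shape[-1] > N:
        raise ValueError("epoch longer than transform length")
    spec = np.fft.rfft(epochs, n=N, axis=-1)[..., bins]
    return np.concatenate([spec.real, spec.imag], axis=-1)
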
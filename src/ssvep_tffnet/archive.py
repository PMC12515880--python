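"""Epoch archive: preprocessed trials plus spectra on disk.

One ``.npz`` container holds ``epochs`` (n x C x T, float32 microvolts),
``labels``, ``subjects`` and ``spectra`` (n x C x 2B, float32); a JSON
sidecar records the preprocessing provenance (band, fs, window, latency,
channels, bin frequencies) and a content hash, so cross-validation runs
can re-read folds cheaply and verify they match their configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .preprocessing import EpochSet
from .spectra import SpectralConfig, band_bins, spectra_for_epochs

__all__ = ["save_archive", "load_archive"]


def _content_hash(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def save_archive(path: str | Path, data: EpochSet,
                 spectral_cfg: SpectralConfig = SpectralConfig(),
                 meta: dict | None = None) -> Path:
    """Write epochs + spectra to ``path`` (.npz) with a JSON sidecar."""
    path = Path(path)
    spectra = spectra_for_epochs(data.epochs, data.fs, spectral_cfg).astype(np.float32)
    epochs = data.epochs.astype(np.float32)
    labels = data.labels.astype(np.int64)
    subjects = data.subjects.astype(np.int64)
    np.savez(path, epochs=epochs, labels=labels, subjects=subjects, spectra=spectra)
    _, _, bin_freqs = band_bins(data.fs, spectral_cfg)
    sidecar = {
        "fs": data.fs,
        "window_s": data.window_s,
        "channel_names": data.channel_names,
        "n_trials": int(data.n_trials),
        "spectral": {"f_lo": spectral_cfg.f_lo, "f_hi": spectral_cfg.f_hi,
                     "df": spectral_cfg.df},
        "bin_freqs_hz": [round(float(f), 6) for f in bin_freqs],
        "content_hash": _content_hash(epochs, labels, subjects, spectra),
    }
    if meta:
        sidecar.update(meta)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def load_archive(path: str | Path) -> tuple[EpochSet, np.ndarray, dict]:
    """Read an archive; returns (EpochSet, spectra, sidecar metadata)."""
    path = Path(path)
    with np.load(path) as zf:
        epochs = zf["epochs"]
        labels = zf["labels"]
        subjects = zf["subjects"]
        spectra = zf["spectra"]
    sidecar_path = path.with_suffix(".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        expect = meta.get("content_hash")
        if expect and expect != _content_hash(epochs, labels, subjects, spectra):
            raise ValueError(f"{path}: content hash mismatch with sidecar")
    data = EpochSet(epochs, labels, subjects,
                    fs=float(meta.get("fs", 0.0)),
                    window_s=float(meta.get("window_s", 0.0)),
                    channel_names=meta.get("channel_names", []))
    return data, spectra, meta
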
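"""Adapters for the public SSVEP dataset layouts.

Three MATLAB-array layouts are supported, identified by ``dataset_id``:

``A12JFPM``
    12-class joint frequency-phase modulation set: one ``s<k>.mat`` per
    subject holding ``eeg`` with axes (target, channel, sample, block);
    8 occipital channels at 256 Hz, 15 blocks, pre-epoched trials.
``BETA``
    40-class set: one ``S<k>.mat`` per subject holding a ``data`` struct
    whose ``EEG`` field has axes (channel, sample, block, condition);
    64 channels at 250 Hz, 4 blocks.
``BENCHMARK``
    40-class set: one ``S<k>.mat`` per subject holding ``data`` with
    axes (channel, sample, condition, block); 64 channels at 250 Hz,
    6 blocks, 6 s epochs including a 0.5 s pre-stimulus interval.

The distributed files contain pre-cut trial segments; each adapter
re-assembles them into a continuous :class:`RawRecording` by
concatenation, placing one stimulus event at each segment's stimulus
onset so that downstream latency-corrected epoching applies uniformly
to real and simulated data.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from scipy.io import loadmat

from .preprocessing import RawRecording, StimulusEvent

__all__ = ["load_dataset", "DATASET_IDS"]

DATASET_IDS = ("A12JFPM", "BETA", "BENCHMARK")

# Stimulus tables of the 12-class paradigm (4 x 3 grid, column-major:
# frequencies step across columns, phases advance by 0.5 pi down rows).
FREQS_12CLASS = np.array([9.25, 11.25, 13.25, 9.75, 11.75, 13.75,
                          10.25, 12.25, 14.25, 10.75, 12.75, 14.75])
PHASES_12CLASS = np.array([0.0, 0.0, 0.0, 0.5, 0.5, 0.5,
                           1.0, 1.0, 1.0, 1.5, 1.5, 1.5]) * np.pi

CHANNELS_12CLASS = ["PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2"]

# 40-class grid in condition-index order (frequency 8 + 0.2 k, phase 0.5 pi k).
FREQS_40CLASS = 8.0 + 0.2 * np.arange(40)
PHASES_40CLASS = np.mod(0.5 * np.pi * np.arange(40), 2 * np.pi)

# Stimulus-onset offset (samples) inside each stored trial segment.
ONSET_OFFSET = {"A12JFPM": 39, "BETA": 125, "BENCHMARK": 125}
EXPECTED_FS = {"A12JFPM": 256.0, "BETA": 250.0, "BENCHMARK": 250.0}
EXPECTED_CHANNELS = {"A12JFPM": 8, "BETA": 64, "BENCHMARK": 64}


def _load_mat(path: Path) -> dict:
    """Read a MATLAB file; the v7.3 dialect is plain HDF5."""
    import h5py

    if h5py.is_hdf5(path):
        out = {}
        with h5py.File(path, "r") as fh:
            for key in fh:
                if isinstance(fh[key], h5py.Dataset):
                    # MATLAB HDF5 stores arrays with reversed axis order
                    out[key] = np.asarray(fh[key]).T
        return out
    return loadmat(path, squeeze_me=False, struct_as_record=False)


def _trials_to_recording(trials: np.ndarray, fs: float, channel_names: list[str],
                         class_of_trial: list[int], freqs: np.ndarray,
                         phases: np.ndarray, onset_offset: int,
                         subject_id: int) -> RawRecording:
    """Concatenate pre-cut trial segments into a continuous recording."""
    events = []
    cursor = 0
    seg_len = trials.shape[-1]
    for k, cls in enumerate(class_of_trial):
        events.append(StimulusEvent(
            onset_sample=cursor + onset_offset,
            class_index=int(cls),
            stim_freq=float(freqs[cls]),
            stim_phase=float(phases[cls]),
        ))
        cursor += seg_len
    data = np.concatenate(list(trials), axis=1)
    return RawRecording(data=data, fs=fs, channel_names=channel_names,
                        events=events, subject_id=subject_id)


def _load_12jfpm_subject(path: Path, subject_id: int) -> RawRecording:
    raw = _load_mat(path)
    if "eeg" not in raw:
        raise ValueError(f"{path}: expected variable 'eeg' (12JFPM layout)")
    eeg = np.asarray(raw["eeg"], dtype=float)
    if eeg.ndim != 4 or eeg.shape[0] != 12 or eeg.shape[1] != EXPECTED_CHANNELS["A12JFPM"]:
        raise ValueError(
            f"{path}: 'eeg' must be (12 targets, 8 channels, samples, blocks); got {eeg.shape}"
        )
    n_targets, _, _, n_blocks = eeg.shape
    trials, classes = [], []
    for block in range(n_blocks):
        for target in range(n_targets):
            trials.append(eeg[target, :, :, block])
            classes.append(target)
    return _trials_to_recording(np.stack(trials), EXPECTED_FS["A12JFPM"],
                                list(CHANNELS_12CLASS), classes,
                                FREQS_12CLASS, PHASES_12CLASS,
                                ONSET_OFFSET["A12JFPM"], subject_id)


def _beta_channel_names(n: int) -> list[str]:
    return [f"CH{i + 1}" for i in range(n)]


def _load_beta_subject(path: Path, subject_id: int) -> RawRecording:
    raw = _load_mat(path)
    if "data" not in raw:
        raise ValueError(f"{path}: expected variable 'data' (BETA layout)")
    entry = raw["data"]
    channel_names = None
    if hasattr(entry, "EEG"):          # scipy mat_struct
        eeg = np.asarray(entry.EEG, dtype=float)
        if hasattr(entry, "suppl_info") and hasattr(entry.suppl_info, "chan"):
            chan = np.ravel(entry.suppl_info.chan)
            if len(chan) == eeg.shape[0]:
                channel_names = [str(np.ravel(c)[0]) for c in chan]
    elif isinstance(entry, np.ndarray) and entry.dtype == object:
        entry = entry.ravel()[0]
        eeg = np.asarray(entry.EEG if hasattr(entry, "EEG") else entry["EEG"],
                         dtype=float)
    else:
        eeg = np.asarray(entry, dtype=float)
    if eeg.ndim != 4 or eeg.shape[0] != EXPECTED_CHANNELS["BETA"] or eeg.shape[3] != 40:
        raise ValueError(
            f"{path}: EEG must be (64 channels, samples, blocks, 40 conditions); got {eeg.shape}"
        )
    if channel_names is None:
        channel_names = _beta_channel_names(eeg.shape[0])
    _, _, n_blocks, n_cond = eeg.shape
    trials, classes = [], []
    for block in range(n_blocks):
        for cond in range(n_cond):
            trials.append(eeg[:, :, block, cond])
            classes.append(cond)
    return _trials_to_recording(np.stack(trials), EXPECTED_FS["BETA"],
                                channel_names, classes,
                                FREQS_40CLASS, PHASES_40CLASS,
                                ONSET_OFFSET["BETA"], subject_id)


def _load_benchmark_subject(path: Path, subject_id: int) -> RawRecording:
    raw = _load_mat(path)
    if "data" not in raw:
        raise ValueError(f"{path}: expected variable 'data' (Benchmark layout)")
    eeg = np.asarray(raw["data"], dtype=float)
    if eeg.ndim != 4 or eeg.shape[0] != EXPECTED_CHANNELS["BENCHMARK"] or eeg.shape[2] != 40:
        raise ValueError(
            f"{path}: 'data' must be (64 channels, samples, 40 conditions, blocks); got {eeg.shape}"
        )
    _, _, n_cond, n_blocks = eeg.shape
    trials, classes = [], []
    for block in range(n_blocks):
        for cond in range(n_cond):
            trials.append(eeg[:, :, cond, block])
            classes.append(cond)
    return _trials_to_recording(np.stack(trials), EXPECTED_FS["BENCHMARK"],
                                _beta_channel_names(eeg.shape[0]), classes,
                                FREQS_40CLASS, PHASES_40CLASS,
                                ONSET_OFFSET["BENCHMARK"], subject_id)


_LOADERS = {
    "A12JFPM": (_load_12jfpm_subject, re.compile(r"^s(\d+)\.mat$", re.IGNORECASE)),
    "BETA": (_load_beta_subject, re.compile(r"^S(\d+)\.mat$", re.IGNORECASE)),
    "BENCHMARK": (_load_benchmark_subject, re.compile(r"^S(\d+)\.mat$", re.IGNORECASE)),
}


def load_dataset(path: str | Path, dataset_id: str,
                 subjects: list[int] | None = None) -> list[RawRecording]:
    """Load one :class:`RawRecording` per subject from a dataset directory.

    ``subjects`` gives 1-based subject indices in the published file
    naming; for BETA the default is the first 35 subjects in original
    index order, elsewhere all available subjects.
    """
    if dataset_id not in DATASET_IDS:
        raise ValueError(f"unknown dataset_id {dataset_id!r}; expected one of {DATASET_IDS}")
    loader, pattern = _LOADERS[dataset_id]
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    available = {}
    for f in root.iterdir():
        m = pattern.match(f.name)
        if m:
            available[int(m.group(1))] = f
    if not available:
        raise FileNotFoundError(
            f"no subject files matching {pattern.pattern!r} in {root}"
        )
    if subjects is None:
        indices = sorted(available)
        if dataset_id == "BETA":
            indices = list(range(1, 36))
    else:
        indices = list(subjects)
    recordings = []
    for idx in indices:
        if idx not in available:
            raise FileNotFoundError(
                f"missing subject file for index {idx} in {root} "
                f"(expected e.g. {'s' if dataset_id == 'A12JFPM' else 'S'}{idx}.mat)"
            )
        recordings.append(loader(available[idx], idx))
    return recordings
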
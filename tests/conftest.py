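import numpy as np
import pytest

import ssvep_tffnet as st


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """Tiny 12-class-style study: 3 subjects, 2 blocks, strong signal."""
    cfg = st.preset_12class(n_subjects=3, n_blocks=2, trial_s=1.4, snr_db=10.0, seed=42)
    return st.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_epochs(small_sim):
    pre = st.PreprocessConfig(band_low=7.0, band_high=64.0, target_fs=256.0,
                              latency_s=0.135, window_s=1.0)
    parts = [st.preprocess_recording(rec, pre) for rec in small_sim.recordings]
    return st.EpochSet.concatenate(parts)
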
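import numpy as np
import pytest
from hypothesis import settings

from therasig import synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from therasig.io_bids import write_synthetic_dataset


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """Synthetic 9-patient dataset mirroring the study's modality
    availability (17 EEG / 16 ECG / 14 EMG-eligible sessions), at desk
    scale: 100-s periods, 512 Hz."""
    root = tmp_path_factory.mktemp("dataset")
    write_synthetic_dataset(root, seed=11, n_patients=9,
                            durations=(100.0, 120.0, 100.0), fs=512.0)
    return root


@pytest.fixture()
def null_eeg_session():
    """EEG with no period effects (all multipliers 1), 60-s periods."""
    profile = synth.EEGEffectProfile()
    return synth.gen_eeg_session(profile, durations=(60, 60, 60), fs=256, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(study_dataset, tmp_path_factory):
    """Full pipeline run over the study-shaped dataset (shared; ~2 min)."""
    from therasig.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("results")
    cfg = RunConfig(seed=1, n_permutations=400)
    return run_pipeline(study_dataset, out, cfg), out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
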
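import numpy as np
import pytest

import wristbci as w

#: A scalp-covering 32-electrode subset of the packaged montage, including
#: every ROI anchor plus frontal/lateral electrodes for artifact modelling.
REDUCED_LABELS = (
    "C3", "C4", "Cz", "FC5", "FC6", "AF3", "AF4", "FCz", "Fpz", "T7", "T8",
    "Fz", "Pz", "O1", "O2", "F3", "F4", "P3", "P4", "CP5", "CP6", "FT7",
    "FT8", "C5", "C6", "F7", "F8", "TP7", "TP8", "PO3", "PO4", "Oz",
)


@pytest.fixture(scope="session")
def full_montage():
    return w.load_default_montage()


@pytest.fixture(scope="session")
def reduced_montage(full_montage):
    return full_montage.subset(REDUCED_LABELS)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_recording(montage, n_trials_per_class=3, seed=0, **overrides):
    """Small synthetic recording for I/O and preprocessing tests."""
    cfg = w.SimConfig(seed=seed, trials_per_class=n_trials_per_class,
                      montage=montage, **overrides)
    return w.generate(cfg)


@pytest.fixture(scope="session")
def small_recording(reduced_montage):
    rec, truth = make_recording(reduced_montage, n_trials_per_class=2, seed=7)
    return rec, truth


@pytest.fixture(scope="session")
def small_trialset(small_recording):
    rec, _ = small_recording
    return w.segment_trials(rec)
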
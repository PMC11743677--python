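import numpy as np
import pytest

from eegmci import (
    CohortConfig,
    PreprocessConfig,
    generate_cohort,
    preprocess,
    segment_epochs,
)
from eegmci.preprocessing import Epoch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """A 3+2-subject, 6-s cohort: enough structure, fast to regenerate."""
    return CohortConfig(n_smci=3, n_pmci=2, duration=6.0, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_epochs(tiny_cohort):
    """Preprocessed 2-s epochs (250 Hz, 500 samples) of the tiny cohort."""
    config = PreprocessConfig()
    epochs = []
    for rec in tiny_cohort:
        epochs.extend(segment_epochs(preprocess(rec, config), config))
    return epochs


def make_epoch(data, fs=250.0, subject_id="S1", group="SMCI", index=0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = [f"ch{i}" for i in range(data.shape[0])]
    return Epoch(
        subject_id=subject_id,
        group=group,
        epoch_index=index,
        channel_names=names,
        fs=fs,
        data=data,
    )
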
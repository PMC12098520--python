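"""Shared fixtures: reduced-model settings and small synthetic cohorts."""

import numpy as np
import pytest

from adgsleep.experiment import preprocess_cohort
from adgsleep.synthetic import SyntheticCohortConfig, generate_cohort

#: reduced architecture used wherever a full-size model is not the point
REDUCED_MODEL = dict(input_size=32, encoder_widths=(8, 16, 32),
                     decoder_channels=32, gru_hidden=16, head_hidden=(32, 16))


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 12 epochs, generated once per session."""
    cfg = SyntheticCohortConfig(n_subjects=3, epochs_per_subject=12,
                                master_seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_tensors(small_cohort):
    """Preprocessed (un-normalized) 32x32 tensors for the small cohort."""
    _, recordings = small_cohort
    return preprocess_cohort(recordings, size=32)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
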
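"""Shared fixtures: small designs and the generating three-region network."""

import numpy as np
import pytest

from dcmv0.forward_model import (
    DEFAULT_SELF_CONNECTION,
    HemodynamicParameters,
    StimulusDesign,
)
from dcmv0.synthetic_data import (
    SyntheticDatasetSpec,
    generate_study_dataset,
    true_connectivity,
)


@pytest.fixture(scope="session")
def study_connectivity():
    return true_connectivity()


@pytest.fixture(scope="session")
def default_hemo():
    return HemodynamicParameters()


@pytest.fixture(scope="session")
def study_dataset():
    """One noisy realisation of the full synthetic study conditions."""
    return generate_study_dataset(SyntheticDatasetSpec(seed=11))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free realisation of the study conditions."""
    return generate_study_dataset(SyntheticDatasetSpec(seed=0, snr=np.inf))


@pytest.fixture
def short_design():
    """A 30-scan block design for fast integration tests."""
    t = np.arange(int(30 * 2.0 / 0.125)) * 0.125
    u = ((t // 20.0).astype(int) % 2 == 0).astype(float)[None]
    return StimulusDesign(tr=2.0, n_scans=30, dt=0.125, inputs=u)


@pytest.fixture
def pulse_design():
    """Single 2-s stimulus in a 32-s window."""
    t = np.arange(int(32.0 / 0.125)) * 0.125
    u = (t < 2.0).astype(float)[None]
    return StimulusDesign(tr=2.0, n_scans=16, dt=0.125, inputs=u)
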
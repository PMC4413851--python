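import numpy as np
import pytest

from sparsemotor.neural_coding import (
    ActivationSpec,
    CodingLayer,
    ThresholdSpec,
    sample_sensory_weights,
)
from sparsemotor.task_model import default_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(20150429)


@pytest.fixture(scope="session")
def full_geometry():
    """The standard task: 8 targets, 3 postures, 5 muscles."""
    return default_geometry()


@pytest.fixture(scope="session")
def tiny_geometry():
    """A minimal task for fast loops: 3 targets, 1 posture, 3 muscles."""
    return default_geometry(K=3, posture_angles=[0.0], n_muscles=3, posture_rotations=[0.0])


@pytest.fixture
def small_coding():
    """N=20 threshold-linear layer with a mid-range threshold."""
    return CodingLayer(
        sample_sensory_weights(20, 7), ThresholdSpec(0.5), ActivationSpec()
    )
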
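from pathlib import Path

import numpy as np
import pytest

import ccssp
from ccssp import synthetic

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture
def tiny_epochs():
    """Two hand-written trials, 3 channels, 4 samples (the CSV fixture twin)."""
    data = np.array(
        [
            [[1.5, -2.25, 0.0, 3.125],
             [0.5, 0.75, -1.0, 2.0],
             [-0.125, 4.5, 2.5, -3.0]],
            [[0.25, 1.0, -0.5, 0.125],
             [-2.0, 3.5, 1.75, 0.0],
             [5.0, -1.25, 0.625, 2.25]],
        ]
    )
    return ccssp.EEGEpochs(
        data=data,
        labels=np.array([1, 2]),
        fs=250.0,
        channel_names=["C3", "Cz", "C4"],
    )


@pytest.fixture
def csv_fixture_dir():
    return FIXTURES / "csv_epochs"


@pytest.fixture(scope="session")
def mi_epochs():
    """Channel-specific narrow-band scenario (seed 0): 120 trials, 8 channels."""
    epochs, _ = synthetic.generate(synthetic.scenario("b", seed=0))
    return epochs


@pytest.fixture(scope="session")
def fitted_model(mi_epochs):
    return ccssp.fit(mi_epochs, k=5, epsilon=1e-5, m=3)


@pytest.fixture(scope="session")
def rsvp_epochs():
    """Imbalanced event-locked scenario (seed 0): 24 targets, 1200 distractors."""
    epochs, truth = synthetic.generate(synthetic.scenario("c", seed=0))
    return epochs, truth
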
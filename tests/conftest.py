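import numpy as np
import pytest

from tempobias import design, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_grid():
    return design.log_spaced_iois(1000, 302, 15)


@pytest.fixture(scope="session")
def pitch_set():
    return design.PitchSet.from_labels(design.DEFAULT_PITCH_LABELS)


@pytest.fixture(scope="session")
def small_study():
    """Ten compliant subjects, fast unordered plans."""
    cfg = simulate.SimulationConfig(n_subjects=10, seed=7, shuffle_order=False)
    return simulate.simulate_study(cfg)
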
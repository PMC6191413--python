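import numpy as np
import pytest

from sharplight.design import make_design
from sharplight.simulate import PopulationSpec, VolumeGrid


@pytest.fixture(scope="session")
def tiny_design():
    """One subject, 2 runs × 12 trials: the smallest useful balanced design."""
    return make_design(1, n_runs=2, trials_per_session=12, seed=0)[0]


@pytest.fixture(scope="session")
def default_design():
    """One subject at the experiment's real dimensions (8 runs × 48 trials)."""
    return make_design(1, n_runs=8, trials_per_session=48, seed=1)[0]


@pytest.fixture
def small_grid():
    return VolumeGrid((5, 5, 5))


def analytic_spec(hypothesis: str, noise_sd: float = 0.0) -> PopulationSpec:
    """Single informative voxel pair with clean round numbers for hand checks."""
    return PopulationSpec(
        informative_region=[(1, 1, 1), (2, 2, 2)],
        preference_assignment={(1, 1, 1): "index", (2, 2, 2): "little"},
        baseline=0.0,
        amp_preferred=2.0,
        amp_nonpreferred=1.0,
        gain=0.5,
        hypothesis=hypothesis,
        noise_sd=noise_sd,
    )


@pytest.fixture
def sharp_spec():
    return analytic_spec("sharpening")


@pytest.fixture
def cancel_spec():
    return analytic_spec("cancellation")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
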
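import numpy as np
import pytest

from tactime.lnp import Condition, NeuronParams
from tactime.synthetic import GroundTruth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def neuron():
    """An adapting, light-responsive neuron with visible baseline firing."""
    return NeuronParams(
        i0=-0.5,
        i1_ss=0.6,
        i1_peak=1.5,
        i2_ss=0.3,
        i2_peak=0.8,
        i3_peak=0.6,
        lambda_max=0.08,
        upsilon=1.0,
    )


@pytest.fixture(scope="session")
def condition_334():
    return Condition(334.0, t_start_ms=-200.0, t_stop_ms=634.0)


@pytest.fixture(scope="session")
def ground_truth():
    """Desk-scale synthetic study: small population, known observer."""
    return GroundTruth(population_size=100, population_seed=7)


@pytest.fixture(scope="session")
def behavior_table(ground_truth):
    from tactime.synthetic import make_behavior_session

    return make_behavior_session(ground_truth, n_trials_per_cell=200, rng=11)
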
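import numpy as np
import pytest

from commuteair import region


@pytest.fixture(scope="session")
def region7():
    return region.make_lattice_region(side=7, cells_per_muni=4, seed=1)


@pytest.fixture(scope="session")
def truth7(region7):
    return region.simulate_truth(region7, region.TruthConfig(), seed=2)


@pytest.fixture(scope="session")
def study7(region7, truth7):
    return region.observe_study(truth7, region7, n_monitors=12, monitor_noise_sd=0.02, seed=3)


def make_input_draws(truth, n_draws, seed):
    """Cheap draw-aligned posterior stand-ins jittered around the truth.

    Used wherever the test exercises the propagation engine rather than the
    upstream fitters.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.true_rates)
    rates = truth.true_rates[None, :] * np.exp(0.05 * rng.standard_normal((n_draws, n)))
    conc = truth.true_field_munis[None, :] * np.exp(0.03 * rng.standard_normal((n_draws, n)))
    effects = truth.true_effects[None, :] + 3e-4 * rng.standard_normal((n_draws, n))
    return rates, conc, effects


@pytest.fixture(scope="session")
def fixture3():
    """The hand-computed 3-municipality configuration."""
    exits = np.zeros((3, 3))
    exits[0, 1] = 3000.0
    exits[1, 0] = 1000.0
    exits[2, 0] = 2000.0
    return {
        "pop": np.array([30000.0, 20000.0, 10000.0]),
        "rates": np.array([0.01, 0.01, 0.02]),
        "conc": np.array([50.0, 30.0, 15.0]),
        "effects": np.array([0.001, 0.0005, 0.002]),
        "exits": exits,
    }
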
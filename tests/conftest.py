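import numpy as np
import pytest

import koniocortex as kc


@pytest.fixture(scope="session")
def bank():
    return kc.make_pattern_bank()


@pytest.fixture()
def fresh_state():
    return kc.init_network(rng=0)


@pytest.fixture(scope="session")
def trained():
    """A physiological network trained for 1000 epochs (seed 0)."""
    spec = kc.ExperimentSpec(name="physiological", epochs_total=1000)
    log, state, schedule = kc.run_experiment(spec, seed=0)
    return log, state, schedule


def random_state(rng):
    """A network state with random-but-valid contents, for oracle tests."""
    state = kc.init_network(rng=rng)
    state.weights.w_tc_ss[:] = rng.uniform(0, 1, state.weights.w_tc_ss.shape)
    state.weights.w_ss_i[:] = rng.uniform(0, 1, state.weights.w_ss_i.shape)
    state.o_tc[:] = rng.uniform(0, 1, state.o_tc.shape)
    state.o_ss[:] = rng.uniform(0, 1, state.o_ss.shape)
    state.s_tc[:] = rng.uniform(0, 1, state.s_tc.shape)
    state.s_ss[:] = rng.uniform(0, 1, state.s_ss.shape)
    state.ana_tc[:] = rng.uniform(0, 1, state.ana_tc.shape)
    state.gabaa_on = bool(rng.integers(2))
    state.ach_on = bool(rng.integers(2))
    state.weights.frozen = bool(rng.integers(2))
    return state
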
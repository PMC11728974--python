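import numpy as np
import pytest

import cyberlipid as cl


@pytest.fixture(scope="session")
def epa_network():
    return cl.build_default_network("EPA")


@pytest.fixture(scope="session")
def dha_network():
    return cl.build_default_network("DHA")


@pytest.fixture(scope="session")
def spec():
    return cl.SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def truth(spec, epa_network):
    return cl.gen_true_params(spec, epa_network)


@pytest.fixture(scope="session")
def profiles(spec):
    return {c: cl.gen_substrate_profiles(c, spec) for c in spec.conditions}


@pytest.fixture(scope="session")
def datasets(spec, epa_network, truth, profiles):
    rng = np.random.default_rng(spec.seed)
    return {
        c: cl.gen_dataset(epa_network, truth, profiles[c], spec, rng=rng)
        for c in spec.conditions
    }


@pytest.fixture(scope="session")
def true_trajectories(epa_network, truth, profiles):
    grid = np.linspace(0.0, 60.0, 241)
    return {
        c: cl.simulate(epa_network, truth, p, t_eval=grid)
        for c, p in profiles.items()
    }
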
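import numpy as np
import pytest

from genembed.design import build_nback_design
from genembed.invert import default_priors
from genembed.network import default_hemodynamics, wm_network
from genembed.synthetic import table1_cohort


@pytest.fixture(scope="session")
def spec():
    return wm_network()


@pytest.fixture(scope="session")
def priors(spec):
    return default_priors(spec)


@pytest.fixture(scope="session")
def hemo():
    return default_hemodynamics(3)


@pytest.fixture(scope="session")
def tiny_design():
    """One block per condition, short rest: ~30 scans for fast inversions."""
    return build_nback_design(n_blocks_per_condition=1, rest_s=16.0)


@pytest.fixture(scope="session")
def small_design():
    """Two blocks per condition: the size used in recovery studies."""
    return build_nback_design(n_blocks_per_condition=2, rest_s=20.0)


@pytest.fixture(scope="session")
def table1():
    return table1_cohort()


@pytest.fixture(scope="session")
def cluster2_params(spec, table1):
    from genembed.network import NeuronalParams

    return NeuronalParams.from_vector(table1.clusters[1].mean, spec)
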
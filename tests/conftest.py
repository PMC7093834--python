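import numpy as np
import pytest

from temine.simulate import (MasterElementConfig, make_master_element,
                             make_species_tree)


@pytest.fixture(scope="session")
def master():
    """Default family master element (~1.5 kb, DD35E, CAGTC, TA TSD)."""
    return make_master_element(MasterElementConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_tree():
    return make_species_tree(4, 400.0, seed=1)
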
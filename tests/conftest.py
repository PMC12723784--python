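import numpy as np
import pytest

from linkzyme.species import Kind, ModelOptions, RateTable


@pytest.fixture
def default_rates():
    return RateTable()


@pytest.fixture
def l_only_rates():
    r = RateTable()
    r.concentrations = {Kind.L: 100.0, Kind.S: 0.0, Kind.P1: 0.0, Kind.P2: 0.0}
    return r


@pytest.fixture
def single_ligand_options():
    return ModelOptions(max_per_kind={Kind.L: 1})


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
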
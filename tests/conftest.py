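import numpy as np
import pandas as pd
import pytest

from ffm.core import ColumnStandardizer
from ffm.schema import DEFAULT_SCHEMA
from ffm.simulate import default_fsp, default_species_specs, generate_specimens
from ffm.trait_data import filter_complete, scale_traits

SEED = 20180606


@pytest.fixture(scope="session")
def schema():
    return DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def community():
    """The default nine-species, 85-specimen synthetic community."""
    return generate_specimens(default_species_specs(), DEFAULT_SCHEMA, seed=SEED)


@pytest.fixture(scope="session")
def fsp():
    return default_fsp()


@pytest.fixture(scope="session")
def z_traits(community):
    scaled = scale_traits(filter_complete(community))
    return ColumnStandardizer().fit_transform(scaled)


@pytest.fixture(scope="session")
def species_of(community):
    return pd.Series({r.specimen_id: r.species for r in community})


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
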
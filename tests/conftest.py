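import numpy as np
import pytest

import premodel as pm
from premodel.modeling import merge_models


@pytest.fixture(scope="session")
def toy_spec():
    return pm.SyntheticComplexSpec()


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    """(receptor, bound-truth peptide, free peptide) of the default toy."""
    return pm.make_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def truth_model(toy_complex):
    receptor, truth, _ = toy_complex
    return merge_models(receptor, truth)


@pytest.fixture(scope="session")
def label_sites(toy_spec):
    return pm.default_label_sites(toy_spec)


@pytest.fixture(scope="session")
def sb_params():
    return pm.SBParameters()


@pytest.fixture(scope="session")
def rc_table():
    return pm.RandomCoilTable.from_package()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
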
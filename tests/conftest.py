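import numpy as np
import pytest

from aunp_radiodose import (
    DielectricTable,
    TumorModel,
    beta_spectrum,
    load_au198,
)


@pytest.fixture(scope="session")
def au198():
    return load_au198()


@pytest.fixture(scope="session")
def au198_spectrum(au198):
    return beta_spectrum(au198, n_points=512)


@pytest.fixture(scope="session")
def gold_table():
    return DielectricTable.load_gold()


@pytest.fixture(scope="session")
def small_tumor():
    return TumorModel(radius_cm=0.25)


@pytest.fixture(scope="session")
def large_tumor():
    return TumorModel(radius_cm=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20160301)
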
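import numpy as np
import pytest
from hypothesis import settings

from velutina import datasets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return datasets.table1_counts()


@pytest.fixture(scope="session")
def habitat():
    return datasets.habitat_records()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140731)
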
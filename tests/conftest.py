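import numpy as np
import pytest

from tsfnn import (
    Dataset,
    SyntheticSpec,
    default_schema,
    generate,
    load_study_fixture,
    make_separable_fixture,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """30 records with mild planted signal, for fast pipeline tests."""
    return generate(SyntheticSpec(n_positive=18, n_negative=12, numeric_effects={16: -1.0}, seed=3))


@pytest.fixture(scope="session")
def separable20() -> Dataset:
    return make_separable_fixture(20, seed=1)


@pytest.fixture(scope="session")
def study_fixture() -> Dataset:
    return load_study_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
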
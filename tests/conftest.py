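import numpy as np
import pytest

from histotex import SyntheticDatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticDatasetSpec.tiny(n_nodular=5, n_micronodular=5, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
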
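import pytest

import gillflux as gf


@pytest.fixture(scope="session")
def compounds():
    return gf.load_compound_table()


@pytest.fixture(scope="session")
def propranolol(compounds):
    return compounds["propranolol"]


@pytest.fixture
def noise_off():
    return gf.NoiseModel.off()
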
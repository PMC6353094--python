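import numpy as np
import pytest

from endopain import load_config


@pytest.fixture(scope="session")
def ps():
    """Default parameter set (published tables + bundled synthetic life table)."""
    return load_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160613)
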
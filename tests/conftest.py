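import numpy as np
import pytest
from hypothesis import settings

from srmkit.corpus import build_corpus

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def corpus3():
    """Three-talker synthetic corpus (the minimum for the speech task)."""
    return build_corpus(talkers=3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
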
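import numpy as np
import pytest

from aavrep import GenomeSpec, ITRSpec, build_genome


@pytest.fixture(scope="session")
def genome():
    """Default annotated 4.7-kb reference with flip left / flop right ITRs."""
    return build_genome(GenomeSpec(seed=7))


@pytest.fixture(scope="session")
def itr_spec():
    return ITRSpec(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
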
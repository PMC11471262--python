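import numpy as np
import pytest

from motifcfg.energy import default_energy_params


@pytest.fixture(scope="session")
def params9():
    """Small-span energy parameters used by the enumeration oracles."""
    return default_energy_params(W=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), n))
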
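import numpy as np
import pytest

from bimod import builtin_scenarios, make_grid


@pytest.fixture(scope="session")
def grid60():
    return make_grid(60)


@pytest.fixture(scope="session")
def grid70():
    return make_grid(70)


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
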
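import numpy as np
import pytest

from bindqtl.motifs import default_core_pwm
from bindqtl.synth import PedigreeSpec, SimConfig, generate_study


@pytest.fixture(scope="session")
def core_pwm():
    return default_core_pwm()


@pytest.fixture(scope="session")
def small_study():
    """A compact default-condition study shared across read-only tests."""
    return generate_study(SimConfig(seed=11, n_sites=150))


@pytest.fixture(scope="session")
def pedigree_spec():
    return PedigreeSpec.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
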
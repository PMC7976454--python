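import numpy as np
import pytest

from wmhmap import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic study shared across read-only tests."""
    cfg = GeneratorConfig(n_subjects=40, grid_dims=(24, 24, 24), seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
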
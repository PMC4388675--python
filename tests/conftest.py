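import numpy as np
import pytest

import finehap as fh


@pytest.fixture(scope="session")
def small_cohort():
    """A modest tagged-locus cohort reused by read-only tests."""
    model = fh.build_locus_model()
    gm, subjects = fh.simulate_case_control(model, 1200, 2400, seed=7)
    return model, gm, subjects


@pytest.fixture(scope="session")
def small_null_cohort():
    """Cohort with every causal effect removed (global null)."""
    model = fh.build_locus_model(causal_ors=(1.0, 1.0, 1.0))
    gm, subjects = fh.simulate_case_control(model, 800, 1600, seed=11)
    return model, gm, subjects


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
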
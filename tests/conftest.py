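import numpy as np
import pytest

import symptomnet as sn


@pytest.fixture(scope="session")
def spec():
    return sn.default_instrument_spec()


@pytest.fixture(scope="session")
def truth():
    """Standard 8-node ground truth: density 0.6, weights 0.05-0.35, one
    negative edge."""
    return sn.default_fixture_truth()


@pytest.fixture(scope="session")
def large_scores(truth):
    """n=5000 synthetic subscale scores from the standard truth (seed 0)."""
    ds = sn.simulate_subscale_scores(truth, n=5000, seed=0)
    return ds.score_table()


@pytest.fixture(scope="session")
def identity_truth():
    return sn.PrecisionSpec(8, np.eye(8))
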
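import numpy as np
import pytest

from eigenformer import EigenGuidedTransformer, make_fixture


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_fixture("tiny", seed=3)


@pytest.fixture(scope="session")
def tiny_prepared(tiny_cohort):
    model = EigenGuidedTransformer.from_tables(
        tiny_cohort.events, tiny_cohort.demographics, alpha=0.9, hidden_target=16
    )
    return model, model.prepare(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
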
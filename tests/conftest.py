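import numpy as np
import pytest

from hemorrhagenet import RunConfig, SimSpec, fit, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """60-sample 32x32 K=3 synthetic cohort shared across read-only tests."""
    return generate_cohort(SimSpec(n=60, image_size=(32, 32), n_classes=3, seed=7))


@pytest.fixture(scope="session")
def tiny_config():
    return RunConfig(image_size=(32, 32), n_classes=3, epochs=4, patience=4,
                     batch_size=32, seed=3)


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort, tiny_config):
    """A briefly trained model (not converged; fixture for structural tests)."""
    model, _ = fit(tiny_cohort, tiny_config)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
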
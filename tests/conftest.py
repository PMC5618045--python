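import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ms_study():
    """A small deterministic MS study shared across modules (binary scoring)."""
    from sicklescreen.synthetic import StudyConfig, generate_study

    return generate_study(
        StudyConfig(n_per_class=8, class_scheme="binary", observer_slope=1000.0, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
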
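import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from lesionseg.phantom import PhantomSpec, make_phantom  # noqa: E402


def small_spec(**overrides) -> PhantomSpec:
    """A fast 32^3 phantom spec used throughout the unit tests."""
    kw = dict(
        grid_shape=(32, 32, 32),
        brain_radius_mm=12.0,
        lesion_radius_mm=4.0,
        lesion_center=(2.0, 1.0, 1.0),
        seed=7,
        n_subjects=1,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_subject():
    return make_phantom(small_spec())[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
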
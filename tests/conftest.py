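import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gap_bottleneck():
    """Bottleneck phantom whose neck is carved out: two disjoint lobes
    separated by a 3-row gap (min inter-lobe pixel distance 4 > th_o=3)."""
    from qwpso.phantoms import PhantomSpec, make_phantom

    return make_phantom(PhantomSpec(shape="bottleneck", size=64, neck_width=3, neck_gap=3))


@pytest.fixture(scope="session")
def suite():
    from qwpso.phantoms import phantom_suite

    return phantom_suite(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
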
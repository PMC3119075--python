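import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def phantom():
    """Default 16x16x4 study phantom: (spec, field, rois, mask)."""
    from dtiplast.phantom import build_phantom, default_phantom_spec

    spec = default_phantom_spec()
    field, rois, mask = build_phantom(spec)
    return spec, field, rois, mask


@pytest.fixture(scope="session")
def scheme():
    from dtiplast.schemes import default_scheme

    return default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20110620 % (2**31))
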
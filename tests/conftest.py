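import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_mosaic():
    """One mid-range synthetic mosaic shared across density tests."""
    from fovea.synthetic import MosaicModel, synth_mosaic

    model = MosaicModel(
        peak_density=200_000.0, sigma_um=100.0, peak_offset_um=(30.0, -20.0), seed=1
    )
    return synth_mosaic(model)
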
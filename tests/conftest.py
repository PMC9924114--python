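import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def clinical_beams():
    """The four clinical beam qualities: (kvp, filtration, HVL spec)."""
    return [
        (70.0, [("Al", 2.0)], ("Al", 2.15)),
        (100.0, [("Cu", 0.1), ("Al", 0.5)], ("Al", 4.25)),
        (125.0, [("Cu", 0.2), ("Al", 2.5)], ("Al", 8.125)),
        (200.0, [("Sn", 0.4), ("Cu", 0.25), ("Al", 1.0)], ("Cu", 1.85)),
    ]


@pytest.fixture(scope="session")
def beam_100kv():
    """Generated 100 kV clinical-quality spectrum."""
    from kvplan import spectrum
    sp = spectrum.generate_tube_spectrum(100.0)
    return spectrum.filter_spectrum(sp, [("Cu", 0.1), ("Al", 0.5)])
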
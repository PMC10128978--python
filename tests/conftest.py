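import pytest
from hypothesis import HealthCheck, settings

from msipcr.cesim import GelModel
from msipcr.panel import default_panel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def gel_screening():
    return GelModel.screening()


@pytest.fixture(scope="session")
def gel_highres():
    return GelModel.highres()


@pytest.fixture(scope="session")
def gel_screening_clean():
    """Noise-free, stutter-free screening gel (round-trip oracle conditions)."""
    return GelModel("screening", peak_sigma_bp=6.0, noise_sd=0.0, stutter_steps=0)


@pytest.fixture(scope="session")
def gel_highres_clean():
    return GelModel("highres", peak_sigma_bp=0.75, noise_sd=0.0, stutter_steps=0)


@pytest.fixture
def germline_alleles(panel):
    return {s.name: [(float(s.germline_size), 1.0)] for s in panel}
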
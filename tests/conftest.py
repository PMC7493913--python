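import pytest
from hypothesis import HealthCheck, settings

from sorbopt import datasets, fit_quadratic

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pb_design():
    """The packaged 15-run Pb(II) Box-Behnken table."""
    return datasets.load_pb_design()


@pytest.fixture(scope="session")
def pb_fit(pb_design):
    return fit_quadratic(pb_design)


@pytest.fixture(scope="session")
def pb_model(pb_fit):
    return pb_fit[0]


@pytest.fixture(scope="session")
def printed_model():
    """Model carrying the published (rounded) coefficients."""
    return datasets.pb_reference_model()
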
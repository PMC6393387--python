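import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mcmpower import (  # noqa: E402
    ANCHOR_PARAMS,
    DesignSpec,
    mediate_correlations,
    scale_to_heritability,
)


@pytest.fixture(scope="session")
def anchor_params():
    """Chain slopes giving h^2 = 1% at maf 0.25 with unit errors."""
    return ANCHOR_PARAMS


@pytest.fixture(scope="session")
def anchor_mc(anchor_params):
    return mediate_correlations(anchor_params)


@pytest.fixture(scope="session")
def scaled_mc(anchor_mc):
    """The anchor chain rescaled to h^2 = 0.1%."""
    return scale_to_heritability(anchor_mc, 0.001)


@pytest.fixture(scope="session")
def srs_design():
    return DesignSpec(scheme="SRS")


@pytest.fixture(scope="session")
def eps_design():
    return DesignSpec(scheme="EPS", trunc_alpha=0.2)
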
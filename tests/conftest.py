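import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bloodpool_dosim.config import (  # noqa: E402
    load_nuclide,
    load_reference_organ_doses,
    load_regulatory_limits,
    load_tissue_weights,
)


@pytest.fixture(scope="session")
def f18():
    return load_nuclide("F-18")


@pytest.fixture(scope="session")
def tc99m():
    return load_nuclide("Tc-99m")


@pytest.fixture(scope="session")
def organ_dose_table():
    """Published adult-male organ-dose coefficients, both scenarios."""
    return load_reference_organ_doses()


@pytest.fixture(scope="session")
def icrp60_weights():
    return load_tissue_weights()


@pytest.fixture(scope="session")
def cfr_limits():
    return load_regulatory_limits()
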
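import pytest
from hypothesis import HealthCheck, settings

from mirtwin import refs
from mirtwin.classify import MatureMiRNA

settings.register_profile(
    "ci", derandomize=True, deadline=None, database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_matures() -> list[MatureMiRNA]:
    return refs.load_reference_matures()


@pytest.fixture(scope="session")
def mir156(reference_matures) -> MatureMiRNA:
    return next(m for m in reference_matures if m.id == "zma-miR156a-5p")


@pytest.fixture(scope="session")
def mir529(reference_matures) -> MatureMiRNA:
    return next(m for m in reference_matures if m.id == "zma-miR529-5p")
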
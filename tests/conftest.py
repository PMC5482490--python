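import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_spec():
    """Busy little transcript exercising all four reaction types."""
    from looptasep import TranscriptSpec

    return TranscriptSpec.uniform(
        30,
        5.0,
        alpha=0.3,
        reinit_rate=1.0,
        release_rate=1.0,
        footprint=5,
        lifetime=50.0,
        id="small",
    )


@pytest.fixture
def tiny_oracle_spec():
    """Lattice small enough for exact master-equation integration."""
    from looptasep import TranscriptSpec

    return TranscriptSpec.uniform(
        12,
        4.0,
        alpha=0.5,
        reinit_rate=1.5,
        release_rate=1.5,
        footprint=3,
        lifetime=40.0,
        id="tiny",
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from looptasep.fixtures import write_fixture_files

    d = tmp_path_factory.mktemp("fixtures")
    paths = write_fixture_files(d, n=8, length_range=(20, 80), seed=42)
    return paths


def z_agree(a, b, se, nsigma=3.0):
    """|a - b| within nsigma standard errors (guarding a zero SE)."""
    return abs(a - b) <= nsigma * max(se, 1e-12)


@pytest.fixture
def assert_within_se():
    return z_agree
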
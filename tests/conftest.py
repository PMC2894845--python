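import numpy as np
import pytest

from hairpinscan.pairwise import ScoringScheme, default_scheme
from hairpinscan.synthetic_data import (
    FamilySpec,
    build_cdf_like,
    build_direct_duplication,
    build_null_family,
    build_orai_like,
)


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return default_scheme()


@pytest.fixture(scope="session")
def cdf_family():
    """One triplicated 6-TMS family at the default 30% divergence."""
    return build_cdf_like(FamilySpec(seed=0))


@pytest.fixture(scope="session")
def orai_family(cdf_family):
    """The hairpin-loss derivative of ``cdf_family``."""
    return build_orai_like(cdf_family, FamilySpec(seed=1000))


@pytest.fixture(scope="session")
def null_family():
    return build_null_family(FamilySpec(seed=0, scenario="null"))


@pytest.fixture(scope="session")
def dup_family():
    return build_direct_duplication(
        FamilySpec(seed=0, scenario="direct_duplication")
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
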
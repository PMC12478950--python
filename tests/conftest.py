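import numpy as np
import pytest

from bimanum.fixtures import FixtureSpec, make_unilateral_fixture
from bimanum.mirroring import MirrorConvention, build_bilateral


@pytest.fixture(scope="session")
def unilateral():
    model, meshes = make_unilateral_fixture(FixtureSpec(seed=7))
    return model, meshes


@pytest.fixture(scope="session")
def model(unilateral):
    return unilateral[0]


@pytest.fixture(scope="session")
def meshes(unilateral):
    return unilateral[1]


@pytest.fixture(scope="session")
def convention():
    return MirrorConvention()


@pytest.fixture(scope="session")
def bilateral(model, convention):
    bil, _ = build_bilateral(model, convention)
    return bil


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
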
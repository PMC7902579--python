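import numpy as np
import pytest

from fetodose.dose_tables import Geometry, builtin_fixture, available_fixtures
from fetodose.interp import make_curve


@pytest.fixture(scope="session")
def ground_total_body_curve():
    return make_curve(builtin_fixture(Geometry.GROUND_PLANE, "total_body"))


@pytest.fixture(scope="session")
def submersion_total_body_curve():
    return make_curve(builtin_fixture(Geometry.AIR_SUBMERSION, "total_body"))


@pytest.fixture(scope="session")
def all_fixture_tables():
    """Every packaged (geometry, organ) table."""
    tables = []
    for geometry, organs in available_fixtures().items():
        for organ in organs:
            tables.append(builtin_fixture(geometry, organ))
    return tables


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
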
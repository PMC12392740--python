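import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from condcap.geometry import (
    assemble_reference_capsid,
    build_dodecahedron_subunit,
    build_icosahedron_subunit,
    build_interaction_table,
)


@pytest.fixture(scope="session")
def dodeca():
    return build_dodecahedron_subunit(1.0)


@pytest.fixture(scope="session")
def ico():
    return build_icosahedron_subunit(1.0)


@pytest.fixture(scope="session")
def dodeca_table():
    return build_interaction_table("dodecahedron", 6.0)


@pytest.fixture(scope="session")
def dodeca_table_rep():
    """Repulsion-only table (eps_ss = 0)."""
    return build_interaction_table("dodecahedron", 0.0)


@pytest.fixture(scope="session")
def ico_table():
    return build_interaction_table("icosahedron", 6.0)


@pytest.fixture(scope="session")
def dodeca_capsid(dodeca):
    return assemble_reference_capsid("dodecahedron", dodeca)


@pytest.fixture(scope="session")
def ico_capsid(ico):
    return assemble_reference_capsid("icosahedron", ico)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
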
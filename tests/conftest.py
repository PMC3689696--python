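import pytest

from ribohet import fixture as fx
from ribohet.variation import profile_variable_sites


@pytest.fixture(scope="session")
def study_alignment():
    """The bundled study fixture (18 clones + 3 database consensus rows)."""
    return fx.reconstruct_alignment(include_consensus=True)


@pytest.fixture(scope="session")
def study_sites(study_alignment):
    return profile_variable_sites(study_alignment, fx.GROUPS)


@pytest.fixture(scope="session")
def study_pair_tables():
    return fx.pair_tables()
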
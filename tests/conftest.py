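import pytest

from mcba.building_blocks import default_acids, default_cores
from mcba.library import build_library
from mcba.spectra import load_table_fixtures


@pytest.fixture(scope="session")
def cores():
    return default_cores()


@pytest.fixture(scope="session")
def acids():
    return default_acids()


@pytest.fixture(scope="session")
def core_by_abbrev(cores):
    return {c.abbreviation: c for c in cores}


@pytest.fixture(scope="session")
def acid_by_name(acids):
    return {a.name: a for a in acids}


@pytest.fixture(scope="session")
def library(cores, acids):
    candidates, _ = build_library(cores, acids)
    return candidates


@pytest.fixture(scope="session")
def isobaric_groups(cores, acids):
    _, groups = build_library(cores, acids)
    return groups


@pytest.fixture(scope="session")
def candidate_lookup(library):
    return {(c.core.abbreviation, c.acid.name): c for c in library}


@pytest.fixture(scope="session")
def table_fixtures():
    return load_table_fixtures()
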
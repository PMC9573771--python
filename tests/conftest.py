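import pytest

from pcbscreen.biotransform import generate_candidates
from pcbscreen.chem import parse_formula
from pcbscreen.synthetic import study_table_fixture


@pytest.fixture(scope="session")
def pcb2():
    return parse_formula("C12H9Cl")


@pytest.fixture(scope="session")
def pcb2_candidates(pcb2):
    return generate_candidates(pcb2)


@pytest.fixture(scope="session")
def fixture_data():
    return study_table_fixture()
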
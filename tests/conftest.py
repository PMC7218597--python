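import pytest

from combokg.claims import extract_conclusive_claims
from combokg.predications import group_by_sentence
from combokg.synthetic import (
    worked_example_abstract,
    worked_example_predications,
)


@pytest.fixture(scope="session")
def gti_abstract():
    return worked_example_abstract()


@pytest.fixture(scope="session")
def gti_claim(gti_abstract):
    claims = extract_conclusive_claims(gti_abstract)
    assert len(claims) == 1
    return claims[0]


@pytest.fixture(scope="session")
def gti_predications():
    return worked_example_predications()


@pytest.fixture(scope="session")
def gti_pset(gti_claim, gti_predications):
    return group_by_sentence(gti_predications)[gti_claim.sentence_id]
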
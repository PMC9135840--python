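import pandas as pd
import pytest

from daakidney import CandidateEntry, make_fixture


@pytest.fixture(scope="session")
def tiny():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def attrition():
    return make_fixture("attrition")


def entry(patient_id="X", t0="2015-06-01", daas=("LDV_SOF",)) -> CandidateEntry:
    return CandidateEntry(patient_id=patient_id, t0=pd.Timestamp(t0),
                          daa_drugs_at_t0=frozenset(daas))
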
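import pytest

from mepephos import load_asarm_region, load_construct
from mepephos.pipeline import _fixture_path

CTERM_45MER = "RRDDSSESSDSGSSSESDGDALGPEQALISEEDLNSAVDHHHHHH"
ASARM_SEQ = "RRDDSSESSDSGSSSESDGD"


@pytest.fixture(scope="session")
def mutant_construct():
    return load_construct(mutant=True)


@pytest.fixture(scope="session")
def wt_construct():
    return load_construct(mutant=False)


@pytest.fixture(scope="session")
def asarm_region():
    return load_asarm_region()


@pytest.fixture(scope="session")
def evidence_path():
    return _fixture_path(None, "table1_evidence.tsv")


@pytest.fixture(scope="session")
def peaks_path():
    return _fixture_path(None, "fig4_peaks_with_fam20c.tsv")


@pytest.fixture(scope="session")
def peaks_after_alp_path():
    return _fixture_path(None, "fig4_peaks_after_alp.tsv")
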
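import pytest
from hypothesis import settings

from neuromine.sequence_io import load_paper_fixtures

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return load_paper_fixtures("table1")


@pytest.fixture(scope="session")
def table2():
    return load_paper_fixtures("table2")


@pytest.fixture(scope="session")
def table3():
    return load_paper_fixtures("table3")


@pytest.fixture(scope="session")
def peptides_by_family(table2):
    out = {}
    for row in table2:
        out.setdefault(row.family, []).append((row.peptide, row.amidated))
    return out
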
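import numpy as np
import pytest

from germ import KnotSpec, SmoothingConfig, fit_agdf, kader_table2


@pytest.fixture(scope="session")
def config10():
    """Standard 10-day smoothing design: quintic, l=1, alpha=0.5."""
    return SmoothingConfig(breaks=(0.0, 2.0, 5.0, 8.0, 10.0))


@pytest.fixture(scope="session")
def kader_records():
    return kader_table2()


@pytest.fixture(scope="session")
def kader_by_id(kader_records):
    return {r.accession: r for r in kader_records}


@pytest.fixture(scope="session")
def kader_agdfs(kader_records, config10):
    """All 32 fixture fits, shared across tests (each fit is deterministic)."""
    return {r.accession: fit_agdf(r, config10) for r in kader_records}


@pytest.fixture(scope="session")
def quintic_spec():
    return KnotSpec((0.0, 2.0, 5.0, 8.0, 10.0), degree=5)
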
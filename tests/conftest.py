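from importlib import resources

import pytest

from myh9rd.domains import DomainArchitecture
from myh9rd.fixture import load_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_fixture()


@pytest.fixture(scope="session")
def arch():
    return DomainArchitecture()


@pytest.fixture(scope="session")
def data_paths():
    data = resources.files("myh9rd.data")
    return {
        "variants": str(data / "table1_variants.tsv"),
        "patients": str(data / "table1_patients.tsv"),
        "registry": str(data / "known_registry.tsv"),
    }


def make_alignment(rows):
    """Aligned FASTA records from raw strings; first row is the reference."""
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    return MultipleSeqAlignment(
        [
            SeqRecord(Seq(row), id=("reference" if i == 0 else f"seq{i}"), description="")
            for i, row in enumerate(rows)
        ]
    )
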
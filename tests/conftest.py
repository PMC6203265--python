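import pytest

from crisprthermo import (
    DuplexKind,
    GuideRNA,
    ScoringConfig,
    TargetSite,
    load_tables,
)
from crisprthermo.weights import unit_weights


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def hybrid(tables):
    return tables[DuplexKind.RNA_DNA]


@pytest.fixture(scope="session")
def dna(tables):
    return tables[DuplexKind.DNA_DNA]


@pytest.fixture(scope="session")
def rna(tables):
    return tables[DuplexKind.RNA_RNA]


@pytest.fixture(scope="session")
def cfg():
    return ScoringConfig()


@pytest.fixture(scope="session")
def unstructured_guide():
    # poly-A guide: no self-structure, so dG_U = 0 and scores decompose cleanly
    return GuideRNA(name="polyA", sequence="A" * 20)


@pytest.fixture()
def perfect_site(unstructured_guide):
    return TargetSite(protospacer=unstructured_guide.as_dna, pam="AGG")


def mutate(protospacer: str, pos: int, base: str) -> str:
    assert protospacer[pos] != base
    return protospacer[:pos] + base + protospacer[pos + 1 :]


@pytest.fixture(scope="session")
def identity_weights():
    return unit_weights()
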
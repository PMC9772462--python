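import random

import pytest
from hypothesis import HealthCheck, settings

from phylocat.formats import GeneRecord, OrganismGeneSet
from phylocat.splitter import GeneFamily

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_org_set(organism_id: str, genes: dict[str, str]) -> OrganismGeneSet:
    """Build an in-memory organism gene set from {gene_name: sequence}."""
    return OrganismGeneSet(
        organism_id=organism_id,
        records={
            g: GeneRecord(g, organism_id, seq) for g, seq in genes.items()
        },
    )


def make_family(gene: str, members: dict[str, str]) -> GeneFamily:
    return GeneFamily(
        gene_name=gene,
        members={org: GeneRecord(gene, org, seq) for org, seq in members.items()},
    )


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(20240901)
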
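import pytest

from codonassoc.catalogue import build_catalogue
from codonassoc.gene_metrics import GeneRecord, compute_gene_record
from codonassoc.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def full_catalogue():
    """The complete 2886-record association catalogue (built once)."""
    return build_catalogue()


@pytest.fixture(scope="session")
def synthetic_genome():
    """A default-parameter synthetic genome at a fixed seed."""
    return simulate_genome(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def synthetic_gene_records(synthetic_genome):
    """Gene metrics computed for every gene of the synthetic genome."""
    return [
        compute_gene_record(GeneRecord(id=gid, cds=seq))
        for gid, seq in zip(synthetic_genome.ids, synthetic_genome.sequences)
    ]
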
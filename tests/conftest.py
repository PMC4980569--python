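import pytest
from hypothesis import HealthCheck, settings

from uniqseq import Chromosome, Genome, build_index, table1_style_fixture
from uniqseq.synthetic import (
    DistinctRandomFlanks,
    PlantDirective,
    SyntheticGenomeSpec,
    generate,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

WORKED_SEQ = "ATGCAAATGCTT"


@pytest.fixture
def worked_genome():
    """The 12-base worked micro-example genome."""
    return Genome([Chromosome("chr1", WORKED_SEQ)])


@pytest.fixture
def worked_index(worked_genome):
    return build_index(worked_genome)


def chrom_seqs(genome):
    return {c.id: c.seq for c in genome}


@pytest.fixture(scope="session")
def synth100k():
    """Seeded 2 x 50 kb background genome with one planted decamer."""
    spec = SyntheticGenomeSpec(
        seed=20,
        chromosomes=(("chr1", 50_000), ("chr2", 50_000)),
        gc_fraction=0.41,
        plants=(PlantDirective("AGACATGCCT", 5, DistinctRandomFlanks(10)),),
    )
    genome, truth = generate(spec)
    return genome, truth, build_index(genome)


@pytest.fixture(scope="session")
def table1():
    genome, truth, query = table1_style_fixture(11)
    return genome, truth, query, build_index(genome)


def random_motif(rng, min_len=1, max_len=25) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list("ACGT"), size=n))
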
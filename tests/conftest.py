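import numpy as np
import pytest

from emda import (
    AlignmentRecord,
    Genome,
    MockCommunity,
    fragment_templates,
    generate_mock_genomes,
)


@pytest.fixture(scope="session")
def five_genomes():
    return generate_mock_genomes(
        5, [5000] * 5, [0.35, 0.45, 0.5, 0.58, 0.65], seed=11
    )


@pytest.fixture(scope="session")
def staircase_community(five_genomes):
    fractions = (0.45, 0.30, 0.15, 0.07, 0.03)
    return MockCommunity(tuple(zip((g.id for g in five_genomes), fractions)))


@pytest.fixture
def template_pool(five_genomes, staircase_community):
    return fragment_templates(
        staircase_community, five_genomes, total_templates=500,
        fragment_length_mean=1000, seed=3,
    )


def make_pairs(n, genome_id="g", genome_length=10_000, read_length=100,
               mapq=60, proper=True, seed=0):
    """Random proper read pairs on one genome, for filter/depth tests."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        m1 = int(rng.integers(0, genome_length - 300))
        records.append(AlignmentRecord(
            pair_id=f"p{i}", genome_id=genome_id, mate1_start=m1,
            mate2_start=m1 + 200, read_length=read_length,
            is_mapped=True, is_proper=proper, mapq=mapq,
        ))
    return records


@pytest.fixture
def random_pairs():
    return make_pairs
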
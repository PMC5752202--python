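import numpy as np
import pytest

from subtelo.genome_model import (
    AnnotatedGenome,
    Chromosome,
    Gene,
    MethylationDomain,
    POSITION_DEPENDENT,
    POSITION_INDEPENDENT,
)
from subtelo.synthetic_data import GeneratorParams, generate_wt_genome


@pytest.fixture
def toy_genome():
    """Two small linear chromosomes with telomere arrays and annotations."""
    return AnnotatedGenome(
        chromosomes=[Chromosome("chrA", 10_000), Chromosome("chrB", 20_000)],
        telomeres={"chrA": (20, 20), "chrB": (20, 20)},
        genes=[
            Gene("chrA", 7_000, 7_500, "+", "gA1"),
            Gene("chrB", 5_000, 5_800, "-", "gB1"),
        ],
        domains=[
            MethylationDomain("chrA", 200, 1_200, POSITION_DEPENDENT),
            MethylationDomain("chrB", 9_000, 10_000, POSITION_INDEPENDENT),
        ],
    )


@pytest.fixture(scope="session")
def small_wt():
    """Small but realistic wild-type genome (lengths-only), session-cached."""
    return generate_wt_genome(
        GeneratorParams(n_chromosomes=3, chrom_length_range=(2_000_000, 3_000_000),
                        domain_count=14, seed=11)
    )


@pytest.fixture(scope="session")
def dense_wt():
    """Denser methylation (>500 fully covered genes) for expression tests."""
    return generate_wt_genome(
        GeneratorParams(seed=6, target_fraction=0.10, domain_count=300)
    )


@pytest.fixture(scope="session")
def default_wt():
    """Default-parameter wild-type genome, session-cached."""
    return generate_wt_genome(GeneratorParams(seed=5))


def label_bases(name, length):
    """Per-base identifier list used by rearrangement oracles."""
    return [(name, i) for i in range(length)]
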
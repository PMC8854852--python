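import pytest

from bolapop import (
    GenotypeRecord,
    GenotypeTable,
    SimulationConfig,
    simulate_allele_pool,
)


def make_table(genotypes, population="p1"):
    """Build a GenotypeTable from [(allele_a, allele_b), ...] or
    [(population, allele_a, allele_b), ...] tuples."""
    records = []
    for i, item in enumerate(genotypes):
        if len(item) == 2:
            pop, a, b = population, *item
        else:
            pop, a, b = item
        records.append(GenotypeRecord(f"s{i + 1}", pop, a, b))
    return GenotypeTable(records)


@pytest.fixture
def tiny_table():
    """Four individuals, two alleles: {A/A, A/B, B/B, A/B} with h_o = 0.5."""
    return make_table([("A", "A"), ("A", "B"), ("B", "B"), ("A", "B")])


@pytest.fixture(scope="session")
def pool():
    """A reusable simulated allele pool under the default study conditions."""
    return simulate_allele_pool(SimulationConfig(seed=11))
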
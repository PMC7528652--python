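import pytest

import yeastrnai as y


@pytest.fixture(scope="session")
def genome():
    """Default synthetic genome: 12 palindromic, 20 non-palindromic and 2
    Y'-like loci plus 3 slice-target genes on 2 chromosomes."""
    return y.make_genome(y.GenomeSpec(seed=11))


@pytest.fixture(scope="session")
def effects(genome):
    return y.PlantedEffects.default(genome, seed=12)


@pytest.fixture(scope="session")
def spikeins():
    return list(y.DEFAULT_SMALLRNA_SPIKEINS)


@pytest.fixture(scope="session")
def study(genome, effects, spikeins):
    """Simulated small-RNA libraries (200k reads per condition) with truth."""
    libs, truth = y.simulate_libraries(genome, effects, spikeins, 200_000, seed=13)
    return libs, truth


@pytest.fixture(scope="session")
def genome_index(genome):
    return y.GenomeIndex(genome.chromosomes)


@pytest.fixture(scope="session")
def mappings(study, genome_index, genome, spikeins):
    libs, _ = study
    out = {}
    for cond, lib in libs.items():
        mapping, _ = y.quantify_sample(cond, lib.species, genome_index,
                                       genome.loci, spikeins)
        out[cond] = mapping
    return out
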
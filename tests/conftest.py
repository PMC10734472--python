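import numpy as np
import pytest

from fgislands import recruitment
from fgislands.pipeline import demo_config
from fgislands.synthetic_community import (
    IslandLocus,
    SimulationConfig,
    build_population,
    simulate_reads,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_population():
    """Two strains of one species, one phosphate island locus (A vs E)."""
    cfg = SimulationConfig(
        seed=42,
        core_length=30_000,
        n_species=1,
        strains_per_species=2,
        island_loci=[IslandLocus("fGIp", 12_000, ("A", "E"))],
        depth_per_strain=20.0,
        samples=[("S1", 1.0), ("S2", 0.002)],
    )
    return build_population(cfg)


@pytest.fixture(scope="session")
def small_reads(small_population):
    return simulate_reads(small_population)


@pytest.fixture(scope="session")
def demo_bundle():
    """The bundled demo scenario: population, reads, per-sample recruitment
    profiles and presence calls against the first strain as reference."""
    cfg = demo_config("scratch/demo_fixture", 42)
    population = build_population(cfg.simulation)
    reads = simulate_reads(population)
    ref_id = sorted(population.genomes)[0]
    reference = population.genomes[ref_id]
    index = recruitment.GenomeIndex(reference)
    profiles = {}
    presence = {}
    for sample_id, sample_reads in reads.items():
        prof = recruitment.recruit(sample_reads, reference, sample_id, index=index)
        profiles[sample_id] = prof
        presence[sample_id] = recruitment.call_presence(prof)
    return {
        "config": cfg,
        "population": population,
        "reads": reads,
        "reference": reference,
        "profiles": profiles,
        "presence": presence,
    }
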
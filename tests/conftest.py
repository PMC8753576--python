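import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pancassette.pipeline import run_cassette_pipeline
from pancassette.simulate import (
    SimulationConfig,
    inject_identifiable_events,
    simulate_pangenome,
)

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


SMALL_CONFIG = dict(
    n_clades=3,
    strains_per_clade=(3, 2, 2),
    backbone_len=6,
    backbone_gene_len_range=(300, 600),
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    """Seven strains, three clades — fast enough for unit tests."""
    return simulate_pangenome(SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_sim_inverted():
    """Same small pan-genome plus the IS-inversion split in one strain."""
    return simulate_pangenome(
        SimulationConfig(**{**SMALL_CONFIG, "inversion_strain": "G01_02"})
    )


def _all_genes(sim):
    return [g for s in sim.strains for g in sim.genes[s]]


@pytest.fixture(scope="session")
def study_null():
    """Study-scale null simulation (108 strains, no recombination) + pipeline."""
    sim = simulate_pangenome(SimulationConfig(seed=1))
    result = run_cassette_pipeline(_all_genes(sim), genomes=sim.genomes)
    return sim, result


@pytest.fixture(scope="session")
def study_events():
    """Study-scale simulation with 5 region swaps and 3 whole-cassette transfers."""
    sim = simulate_pangenome(SimulationConfig(seed=2))
    inject_identifiable_events(
        sim, np.random.default_rng(123), n_region_swaps=5, n_whole_transfers=3
    )
    result = run_cassette_pipeline(_all_genes(sim), genomes=sim.genomes)
    return sim, result
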
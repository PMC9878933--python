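import numpy as np
import pytest

from springbloom import mobilome as mob
from springbloom import synth


@pytest.fixture(scope="session")
def design():
    return synth.SamplingDesign(rng_seed=1)


@pytest.fixture(scope="session")
def kinetics_truth(design):
    """One taxon at gross doubling time 37 h with 55% mortality, plus a
    static background, propagated over the 13-day epilimnion grid."""
    return synth.simulate_community(synth.kinetics_scenario(), design)


@pytest.fixture(scope="session")
def pattern_truth(design):
    """Twelve taxa, three per succession archetype A-D."""
    specs = synth.pattern_taxa(n_per_category=3, seed=3)
    return synth.simulate_community(specs, design)


@pytest.fixture(scope="session")
def small_phage_pop():
    """Three families x three members at planted identities."""
    return synth.synth_phage_population(
        [3, 3, 3], identity_targets=[0.97, 0.98, 1.0], seed=11,
        length_range=(12_000, 20_000))


@pytest.fixture(scope="session")
def host_fixture(small_phage_pop):
    return synth.synth_hosts_and_bins(small_phage_pop, seed=13, n_hosts=6,
                                      host_length=20_000)


@pytest.fixture(scope="session")
def phage_30kb():
    rng = np.random.default_rng(21)
    return mob.GenomeRecord("phage30", synth.random_genome(30_000, rng))
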
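import pytest

from bulkmap import synthetic_data as sd


@pytest.fixture(scope="session")
def scenario1() -> sd.Scenario:
    """One fully simulated default experiment, shared across tests."""
    return sd.simulate_scenario(seed=1)


@pytest.fixture(scope="session")
def tiny_map() -> sd.GeneticMapConfig:
    """A two-contig, 20-cM toy map: anchors at 5 and 15 cM, one marker each."""
    return sd.GeneticMapConfig(
        chromosomes=(("1H", 20.0),),
        markers_per_cm=0.1,
        contigs_per_chromosome=2,
        unanchored_fraction=0.0,
        seed=0,
    )
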
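import numpy as np
import pytest

from hybridkit import sim


@pytest.fixture(scope="session")
def small_layout() -> sim.GenomeLayout:
    """Three short scaffolds with recombination visible at this scale."""
    return sim.GenomeLayout(
        scaffolds=(("s1", 100_000), ("s2", 80_000), ("s3", 50_000)),
        morgans_per_bp=1e-5,
    )


@pytest.fixture(scope="session")
def ten_scaffold_layout() -> sim.GenomeLayout:
    return sim.default_layout(n_scaffolds=10, scaffold_bp=1_000_000, morgans_per_bp=1e-6)


@pytest.fixture(scope="session")
def diag_freqs(small_layout) -> sim.SpeciesFrequencies:
    """Fully diagnostic frequencies: every site fixed between A and B."""
    return sim.build_species_frequencies(
        small_layout, n_sites=500, fst=0.3, prop_diagnostic=1.0, seed=11)


@pytest.fixture(scope="session")
def mixed_freqs(small_layout) -> sim.SpeciesFrequencies:
    """30% diagnostic sites plus Balding-Nichols background divergence."""
    return sim.build_species_frequencies(
        small_layout, n_sites=2_000, fst=0.3, prop_diagnostic=0.3, seed=7)


@pytest.fixture(scope="session")
def cohort(small_layout, mixed_freqs) -> sim.SimulatedDataset:
    """Panels of 5+4 parentals plus one F1, two BC1s and a later-generation hybrid."""
    pedigrees = [
        ("F1_1", sim.PedigreeSpec(kind="F1")),
        ("BC1_B_1", sim.PedigreeSpec(kind="BC1", backcross_to="B")),
        ("BC1_A_1", sim.PedigreeSpec(kind="BC1", backcross_to="A")),
        ("LG_1", sim.PedigreeSpec(kind="later_generation", g=5)),
    ]
    return sim.simulate_dataset(
        small_layout, mixed_freqs, {"A": 5, "B": 4}, pedigrees,
        seed=23, missing_rate=0.03, with_depth=True,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
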
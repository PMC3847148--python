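import pytest

from synlethscreen import SimulationConfig, assign_labels, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """Two-dataset bundle with a strong planted effect (fast to screen)."""
    return simulate_bundle(
        SimulationConfig(
            n_genes=120,
            n_kinases=30,
            n_planted=6,
            effect_size=2.0,
            n_datasets=2,
            n_compounds=12,
            n_target_compounds=4,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_labels(small_bundle):
    return assign_labels(small_bundle.mutations, small_bundle.datasets[0].samples)
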
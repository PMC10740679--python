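import pytest

from splicescape import synthetic_data


@pytest.fixture(scope="session")
def default_sim():
    """The default simulated study: 3 phenotypes, 5/3/3 samples, planted signal."""
    return synthetic_data.simulate()


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, dropout-free simulation: planted truth must be recovered exactly."""
    config = synthetic_data.SimulationConfig(
        n_genes=600, noise_sd=0.0, dropout_tpm=0.0
    )
    return synthetic_data.simulate(config)


@pytest.fixture(scope="session")
def small_sim():
    """A small-but-complete simulation for fast structural tests."""
    config = synthetic_data.SimulationConfig(
        n_genes=150,
        n_specific_isoforms=4,
        das_shift_sets=(
            synthetic_data.DasShiftSpec("SHIFT_A", 6, 2, "HepG2"),
            synthetic_data.DasShiftSpec("SHIFT_B", 6, 2, "liver"),
        ),
        n_null_sets=5,
        null_set_size=8,
        library_size=30_000,
    )
    return synthetic_data.simulate(config)
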
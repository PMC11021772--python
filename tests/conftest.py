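import numpy as np
import pytest

from kicscreen.synthetic import SyntheticScreenConfig, generate_screen


@pytest.fixture(scope="session")
def default_screen():
    """One full-size synthetic screen shared by read-only tests."""
    return generate_screen(SyntheticScreenConfig(random_seed=42))


@pytest.fixture
def small_config():
    """Reduced screen for tests that generate many replicates."""
    return SyntheticScreenConfig(
        random_seed=0,
        n_proteins=30,
        protein_length_range=(100, 200),
        n_library_peptides=60,
        n_true_substrates=12,
        n_seeds_per_screen=(20, 25),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
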
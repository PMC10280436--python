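import numpy as np
import pytest

from tsskit.dataset import WindowParams, build_dataset
from tsskit.synthetic import SyntheticGenomeConfig, generate_fixture

SMALL_WINDOW = WindowParams(upstream_flank=10, codon_length=3, downstream_flank=7)


@pytest.fixture(scope="session")
def default_fixture():
    """2 chromosomes x 50 kb, 20 transcripts, default 700/303 margins."""
    config = SyntheticGenomeConfig(
        n_chromosomes=2, chromosome_length=50_000, n_transcripts=20, seed=7
    )
    return generate_fixture(config), config


@pytest.fixture(scope="session")
def small_window_fixture():
    """Compact fixture for fast model-level tests: 20-base windows."""
    config = SyntheticGenomeConfig(
        n_chromosomes=3,
        chromosome_length=8_000,
        n_transcripts=45,
        motif="TATAAAGG",
        motif_noise=0.05,
        background_gc=0.5,
        seed=13,
        upstream_margin=15,
        downstream_margin=15,
    )
    return generate_fixture(config), config


@pytest.fixture(scope="session")
def small_dataset(small_window_fixture):
    (assembly, annotation), _ = small_window_fixture
    return build_dataset(assembly, annotation, SMALL_WINDOW, 10, seed=5)


@pytest.fixture(scope="session")
def random_sequences():
    rng = np.random.default_rng(42)
    return ["".join(rng.choice(list("ACGT"), 60)) for _ in range(30)]
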
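import numpy as np
import pytest

from metagc.synthetic_community import (
    EnvironmentProfile,
    PhylumProfile,
    SyntheticConfig,
    default_phylum_profiles,
    generate_collection,
)


@pytest.fixture(scope="session")
def small_collection():
    """A small two-environment collection exercising coding reads."""
    cfg = SyntheticConfig(
        phyla=[
            PhylumProfile("Alpha", 45.0, 6.0, coding_fraction=0.5),
            PhylumProfile("Beta", 60.0, 6.0, coding_fraction=0.5),
            PhylumProfile("Gamma", 52.0, 6.0),
        ],
        environments=[
            EnvironmentProfile("soil", n_samples=4),
            EnvironmentProfile("water", n_samples=4, gc_offset=3.0),
        ],
        reads_per_sample=120,
        read_length=120,
        offset_sd=1.0,
        confidence_noise=0.1,
        seed=42,
    )
    return cfg, generate_collection(cfg)


@pytest.fixture(scope="session")
def gut_like_matrix():
    """Matrix-level draw from the ten-phylum coupled generator."""
    from metagc.synthetic_community import simulate_gc_matrix

    cfg = SyntheticConfig(
        phyla=default_phylum_profiles(),
        environments=[EnvironmentProfile("gut", n_samples=60)],
        reads_per_sample=300,
        offset_sd=3.0,
        seed=5,
    )
    matrix, abundance, offsets = simulate_gc_matrix(cfg)
    return matrix, abundance, offsets


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
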
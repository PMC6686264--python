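import numpy as np
import pytest

from platfuse import (EncoderSpec, SyntheticConfig, prepare_normalized,
                      simulate_cohort, train_encoder_bundle)

# desk-scale encoder configuration used throughout the suite
DESK_SIZES = (64, 48, 32, 16)
DESK_EPOCHS = 200
DESK_LR = 1e-3


def desk_encoder_spec(seed: int, epochs: int = DESK_EPOCHS) -> EncoderSpec:
    return EncoderSpec(input_dim=300, encoder_layer_sizes=DESK_SIZES,
                       epochs=epochs, learning_rate=DESK_LR, seed=seed)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort: raw matrices, map, endpoints, truth."""
    return simulate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_cohort(cohort):
    a, b, gene_map, endpoints, truth = cohort
    a_n, b_n, params = prepare_normalized(a, b, gene_map)
    return a_n, b_n, endpoints, truth


@pytest.fixture(scope="session")
def bundle(normalized_cohort):
    """All four encoding networks trained once at desk scale."""
    a_n, b_n, _, _ = normalized_cohort
    return train_encoder_bundle(a_n, b_n, desk_encoder_spec(seed=11, epochs=150))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
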
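import numpy as np
import pytest

from spikecast import ModelConfig, SimConfig, TrainConfig, generate_dataset
from spikecast.transformer import ModelState

MODALITY_WEIGHTS = {m: 1.0 for m in ("neural", "wheel", "whisker", "choice", "block")}


def micro_sim_config(**overrides) -> SimConfig:
    """A deliberately tiny dataset config for fast structural tests."""
    base = dict(
        n_sessions=1,
        n_neurons_per_session=12,
        n_trials=30,
        n_bins=10,
        latent_dim=3,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


def micro_model_config(**overrides) -> ModelConfig:
    base = dict(width=16, n_layers=1, n_heads=2, d_ff=32, dropout=0.0, seed=0)
    base.update(overrides)
    return ModelConfig(**base)


def micro_train_config(**overrides) -> TrainConfig:
    base = dict(epochs=3, batch_size=8, lr=3e-3, seed=0, patience=3)
    base.update(overrides)
    return TrainConfig(**base)


@pytest.fixture
def micro_bundle():
    return generate_dataset(micro_sim_config())[0]


@pytest.fixture
def micro_state(micro_bundle):
    state = ModelState(micro_model_config())
    state.register_session(micro_bundle.session_id, micro_bundle.n_neurons)
    return state


@pytest.fixture
def rng():
    return np.random.default_rng(0)
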
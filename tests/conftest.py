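import numpy as np
import pytest

from ecgmark.synthetic_ecg import DatasetSpec, generate_dataset, synthesize_beat
from ecgmark.vae_core import VAE, VAEConfig, train


@pytest.fixture(scope="session")
def clean_beat():
    return synthesize_beat(n_samples=90, sampling_rate=250.0)


@pytest.fixture(scope="session")
def trained_model():
    """One converged VAE + its dataset, shared across tests (noiseless data)."""
    spec = DatasetSpec(n_signals=200, noise_factor=0.0, seed=11)
    dataset = generate_dataset(spec=spec, n_samples=90)
    cfg = VAEConfig(seed=11)
    model = VAE(cfg)
    train(model, dataset.train, cfg)
    return model, dataset


@pytest.fixture()
def tiny_config():
    """Small dimensions so finite-difference gradient checks stay cheap."""
    return VAEConfig(input_dim=8, latent_dim=3, hidden_dims=(6, 5), seed=3)


@pytest.fixture(scope="session")
def zero_model():
    cfg = VAEConfig(input_dim=12, latent_dim=4, hidden_dims=(6, 5), seed=0)
    model = VAE(cfg)
    for k in model.params:
        model.params[k] = np.zeros_like(model.params[k])
    return model
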
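import numpy as np
import pytest

from dtifuse.config import PipelineConfig
from dtifuse.data import InteractionNetwork
from dtifuse.simulate import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Small pipeline settings so end-to-end tests stay fast."""
    return PipelineConfig(
        kmer_k=2,
        gf_dim=8,
        gf_max_iterations=150,
        sae_hidden_dims=(32,),
        sae_code_dim=16,
        sae_epochs=8,
        cnn_n_kernels=4,
        cnn_kernel_len=5,
        cnn_epochs=40,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small noise-free synthetic benchmark shared across tests."""
    cfg = SyntheticConfig(
        n_drugs=30,
        n_targets=24,
        interaction_density_target=0.1,
        label_noise=0.0,
        fp_length=64,
        seq_length_range=(60, 120),
        seed=11,
    )
    network, drugs, proteins, U, V = simulate_dataset(cfg)
    return {
        "config": cfg,
        "network": network,
        "drugs": drugs,
        "proteins": proteins,
        "U": U,
        "V": V,
    }


@pytest.fixture
def small_network() -> InteractionNetwork:
    A = np.array([[1, 0, 1], [1, 0, 0]], dtype=np.int8)
    return InteractionNetwork(A, ["d1", "d2"], ["p1", "p2", "p3"])
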
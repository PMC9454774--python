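import numpy as np
import pytest

from gocapgan.gan import GanConfig
from gocapgan.synthetic import SyntheticDesign, generate_corpus


@pytest.fixture
def tiny_gan_config():
    """Smallest GAN that still exercises every architectural element."""
    return GanConfig(
        batch_size=8, seq_len=16, noise_dim=12, epochs=1, channels=8,
        capsule_conv_channels=8, primary_capsule_dim=4, out_capsules=3,
        out_capsule_dim=4, kernel_size=5, n_critic=2, seed=7,
    )


@pytest.fixture
def tiny_corpus():
    """Planted-motif corpus small enough for second-scale tests."""
    design = SyntheticDesign(
        n_classes=4, n_proteins=48, min_len=20, max_len=32,
        labels_min=1, labels_max=2, motif_len_min=4, motif_len_max=5, seed=11,
    )
    return generate_corpus(design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
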
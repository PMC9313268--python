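import numpy as np
import pytest

from clearquant import (
    NoiseModel,
    ProtocolParams,
    StackPhantomSpec,
    TransmittancePhantomSpec,
    generate_fluorescence_stack,
    generate_transmittance_pair,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_pairs(mu, thickness_mm=1.0, n_images=3, *, noise_sigma_frac=0.0,
               illumination=20000.0, vignette=0.0, size=(256, 256),
               seed=0, sample_id="s0", condition="cond"):
    """Helper: generate one sample's transmittance pairs from the phantom."""
    sigma = noise_sigma_frac * illumination
    noise = NoiseModel("gaussian", sigma=sigma) if sigma > 0 else NoiseModel()
    pairs = []
    for i in range(n_images):
        spec = TransmittancePhantomSpec(
            image_height_px=size[0], image_width_px=size[1], mu_true=mu,
            thickness_mm=thickness_mm, illumination_level=illumination,
            vignette_strength=vignette, noise_model=noise,
            seed=seed * 1000 + i,
        )
        pairs.append(
            generate_transmittance_pair(spec, sample_id=sample_id,
                                        condition=condition).pair
        )
    return pairs


@pytest.fixture
def noisefree_pairs():
    return make_pairs(mu=2.0, thickness_mm=1.5)


@pytest.fixture
def corrupted_stack_phantom():
    spec = StackPhantomSpec(
        shape_zyx=(8, 64, 64), n_nuclei=15, n_vessels=2,
        stripe_axis=2, stripe_amplitude=0.2, stripe_period_px=8.0,
        impulse_fraction=0.01, background_level=0.2, seed=42,
    )
    return generate_fluorescence_stack(spec)
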
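import numpy as np
import pytest

from vflatent import (CohortParams, VAEConfig, build_24_2_mask,
                      images_from_series, simulate_cohort, train)


@pytest.fixture(scope="session")
def mask():
    return build_24_2_mask()


@pytest.fixture(scope="session")
def small_cohort():
    """40 simulated patients with ground truth (fast, deterministic)."""
    return simulate_cohort(40, seed=3)


@pytest.fixture(scope="session")
def small_images(small_cohort):
    cohort, _ = small_cohort
    return images_from_series(cohort)


@pytest.fixture(scope="session")
def tiny_model(small_images):
    """A small 2-D-latent model trained for a few epochs (shape/contract tests)."""
    cfg = VAEConfig(latent_dim=2, encoder_channels=(8, 12), epochs=8,
                    batch_size=50, seed=0)
    return train(small_images[:250], small_images[250:288], cfg)
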
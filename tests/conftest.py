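import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dtseg.denoise import denoise_image
from dtseg.phantom import PhantomSpec, add_noise, generate_phantom

EASY_SPEC = dict(
    height=128,
    width=128,
    n_classes=4,
    tumor_count_range=(1, 2),
    class_means=(0.05, 0.95, 0.35, 0.75),
    class_texture_sd=(0.02, 0.02, 0.02, 0.02),
)

TWO_CLASS_SPEC = dict(
    height=128,
    width=128,
    n_classes=2,
    tumor_count_range=(0, 0),
    class_means=(0.3, 0.7),
    class_texture_sd=(0.05, 0.05),
)


@pytest.fixture(scope="session")
def easy_phantom():
    """One clean/noisy/truth triple of the well-separated 4-class phantom."""
    spec = PhantomSpec(seed=7, **EASY_SPEC)
    clean, truth = generate_phantom(spec)
    noisy = add_noise(clean, 0.05, seed=17)
    return clean, noisy, truth


@pytest.fixture(scope="session")
def denoised_easy_phantom(easy_phantom):
    clean, noisy, truth = easy_phantom
    return denoise_image(noisy), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
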
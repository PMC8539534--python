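import numpy as np
import pytest

from hsablate.synthetic import SceneParams, generate_ablation, generate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale scene at the default study conditions."""
    return SceneParams(seed=11)


@pytest.fixture(scope="session")
def ablation(small_params):
    """One generated procedure shared by read-only tests."""
    return generate_ablation(small_params, ablation_id=0)


@pytest.fixture(scope="session")
def study(small_params):
    """A six-procedure synthetic study."""
    return generate_study(small_params, 6)


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, perfectly aligned conditions (for identity checks)."""
    return SceneParams(
        seed=5,
        noise_sd=0.0,
        frame_noise_sd=0.0,
        misalignment=0.0,
        n_specularities=0,
    )


@pytest.fixture(scope="session")
def clean_ablation(clean_params):
    return generate_ablation(clean_params, ablation_id=0)
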
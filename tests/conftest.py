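import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glioseg.phantom import PhantomSpec, generate_phantom
from glioseg.volumes import Modality

settings.register_profile(
    "glioseg",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("glioseg")


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A scaled-down head phantom (64x64x12) for fast unit tests."""
    defaults = dict(
        grid_shape=(64, 64, 12),
        voxel_spacing=(0.9, 0.9, 5.0),
        brain_center=(32.0, 32.0, 6.0),
        brain_radii=(27.0, 22.0, 5.0),
        skull_thickness=2.0,
        scalp_thickness=2.0,
        gm_thickness=3.0,
        ventricle_centers=((28.0, 32.0, 6.0), (36.0, 32.0, 6.0)),
        ventricle_radii=(2.5, 5.0, 1.5),
        lesion_center=(18.0, 25.0, 6.0),
        core_radii=(3.0, 3.0, 1.2),
        rim_radii={
            Modality.T2: (6.5, 6.5, 2.2),
            Modality.FLAIR: (7.5, 7.5, 2.5),
            Modality.PMAP: (5.5, 5.5, 2.0),
        },
        noise_sigma=0.03,
        rng_seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(small_phantom_spec(noise_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20180918)


def random_spd_tensor(rng: np.random.Generator, scale: float = 1e-3) -> np.ndarray:
    """Random symmetric positive-definite 3x3 diffusion-like tensor."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    lam = rng.uniform(0.2, 3.0, size=3) * scale
    return q @ np.diag(lam) @ q.T
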
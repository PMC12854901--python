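"""Shared fixtures: small, fast synthetic scenes."""
import numpy as np
import pytest

from condensate_quant import SceneParams, VolumetricImage, generate_scene


@pytest.fixture(scope="session")
def clean_params() -> SceneParams:
    """Noise- and texture-free two-phase-plus-condensates scene."""
    return SceneParams(
        grid_shape=(12, 48, 48),
        voxel_size=(0.2, 0.08, 0.08),
        nucleus_axes=(1.0, 1.7, 1.7),
        c_tot=100.0,
        partition_coefficient=5.0,
        volume_fraction=0.1,
        n_condensates=2,
        condensate_radius_mean=0.5,
        condensate_radius_sd=0.05,
        background_level=0.0,
        psf_sigma=0.0,
        noise_model="none",
        heterogeneity=0.0,
        background_heterogeneity=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def clean_scene(clean_params):
    return generate_scene(clean_params)


@pytest.fixture(scope="session")
def default_scene():
    """One realistic scene at the generator's default study conditions."""
    return generate_scene(SceneParams(rng_seed=42))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_image(data, voxel_size=(0.2, 0.08, 0.08), channel="ch1") -> VolumetricImage:
    return VolumetricImage(data=np.asarray(data, dtype=float), voxel_size=voxel_size, channel=channel)
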
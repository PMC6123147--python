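"""Shared fixtures: small, fast synthetic scenes with known ground truth."""

import warnings

import numpy as np
import pytest

from epidtrack import (
    GrayImage,
    SceneConfig,
    default_phantom_scene,
    lorentzian_psf,
    make_qc3_phantom,
)
from epidtrack.image import degrade_image


@pytest.fixture(autouse=True)
def _quiet_psf_truncation_warning():
    # the default PSF support intentionally truncates the heavy Lorentzian tail
    # and warns about it; tests exercise that warning explicitly where relevant
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="PSF support half-width")
        yield


@pytest.fixture(scope="session")
def psf_default():
    return lorentzian_psf(0.5, pixel_spacing_mm=0.784)


@pytest.fixture(scope="session")
def small_phantom_scene():
    return SceneConfig(image_shape=(192, 256), seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_scene):
    return make_qc3_phantom(small_phantom_scene)


@pytest.fixture(scope="session")
def degraded_small_phantom(small_phantom, small_phantom_scene, psf_default):
    pristine, gt = small_phantom
    g = degrade_image(
        pristine, psf_default, small_phantom_scene.noise_sd,
        small_phantom_scene.seed, quantize=True,
    )
    return g, gt


@pytest.fixture(scope="session")
def small_cine_scene():
    from epidtrack import sinusoidal_trajectory

    return SceneConfig(
        image_shape=(96, 128),
        background_level=600.0,
        tumor_contrast=0.05,
        tumor_radius_px=6.0,
        trajectory=sinusoidal_trajectory(8),
        noise_sd=2.0,
        seed=11,
    )


@pytest.fixture
def textured_frame():
    """A deterministic textured frame for tracking tests."""
    rng = np.random.default_rng(42)
    base = 100 + 20 * rng.random((64, 80))
    rr, cc = np.mgrid[0:64, 0:80]
    base += 30 * np.exp(-(((rr - 32) / 5.0) ** 2 + ((cc - 40) / 5.0) ** 2))
    return GrayImage(base, 0.784)
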
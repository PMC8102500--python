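import numpy as np
import pytest

from nequant import NucleusSpec, SceneSpec


@pytest.fixture
def single_nucleus_scene() -> SceneSpec:
    """One tilted elliptical nucleus with a 2x rim on a 96x96 field, noise-free."""
    return SceneSpec(
        image_shape=(96, 96),
        nuclei=[NucleusSpec(center=(48, 48), semi_axes=(30, 24), angle_deg=15)],
        rim_contrast=2.0,
        noise_sigma=0.0,
        seed=11,
    )


@pytest.fixture
def two_nuclei_scene() -> SceneSpec:
    return SceneSpec(
        image_shape=(128, 192),
        nuclei=[
            NucleusSpec(center=(60, 50), semi_axes=(28, 22), angle_deg=0),
            NucleusSpec(center=(64, 140), semi_axes=(24, 26), angle_deg=40),
        ],
        rim_contrast=1.5,
        noise_sigma=1.0,
        seed=4,
    )


@pytest.fixture
def frap_geometry() -> SceneSpec:
    """Structure large relative to the bleach ROI, as in a real acquisition."""
    return SceneSpec(image_shape=(80, 80),
                     nuclei=[NucleusSpec(center=(40, 40), semi_axes=(30, 26))])


@pytest.fixture
def background_roi() -> np.ndarray:
    bg = np.zeros((80, 80), dtype=bool)
    bg[:5, :5] = True
    return bg
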
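import numpy as np
import pytest

from ctmorph.core import VolumeImage
from ctmorph.phantom import PhantomSpec, generate_tissue


@pytest.fixture(scope="session")
def enhanced_phantom_128():
    """Contrast-mode 128³ phantom, porosity 0.10, seed 1 (shared, read-only)."""
    spec = PhantomSpec(
        shape=(128, 128, 128),
        voxel_size=2.5,
        target_porosity=0.10,
        contrast_mode=True,
        noise_sd=8.0,
        random_seed=1,
    )
    return generate_tissue(spec)


@pytest.fixture(scope="session")
def enhanced_phantom_64():
    spec = PhantomSpec(
        shape=(64, 64, 64),
        voxel_size=2.5,
        target_porosity=0.10,
        mean_cell_diameter=45.0,
        contrast_mode=True,
        noise_sd=8.0,
        random_seed=11,
    )
    return generate_tissue(spec)


@pytest.fixture(scope="session")
def structures_phantom():
    """Elongated contrast phantom with a vasculature tube (spanning >500 µm
    in z) and 3 compact stone-cell clusters."""
    from ctmorph.phantom import add_inclusions

    spec = PhantomSpec(
        shape=(224, 96, 96),
        voxel_size=2.5,
        target_porosity=0.08,
        contrast_mode=True,
        noise_sd=5.0,
        random_seed=21,
    )
    out = generate_tissue(spec)
    return add_inclusions(
        out, vessel_radius=25.0, cluster_diameter=80.0, n_clusters=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def digitized_ball(radius: int, pad: int = 2) -> np.ndarray:
    n = 2 * radius + 1 + 2 * pad
    c = n // 2
    z, y, x = np.ogrid[:n, :n, :n]
    return ((z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2) <= radius * radius


@pytest.fixture
def ball_factory():
    return digitized_ball


def make_volume(data: np.ndarray, voxel_size: float = 2.5) -> VolumeImage:
    return VolumeImage(data=data.astype(np.uint8), voxel_size=voxel_size, bit_depth=8)
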
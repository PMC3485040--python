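import numpy as np
import pytest
from scipy import ndimage

import scanqa as sq


@pytest.fixture(scope="session")
def smooth_head_phantom():
    """Smooth two-region structural phantom suitable for registration."""
    spec = sq.StructuralPhantomSpec(
        shape=(48, 48, 48),
        voxel_dims=(1.0, 1.0, 1.0),
        regions=[
            sq.EllipsoidRegion(1, (24, 28, 24), (14, 11, 12), 900.0, "head"),
            sq.EllipsoidRegion(2, (24, 9, 24), (4, 3, 3), 500.0, "blob"),
        ],
        background_noise_sd=0.0,
    )
    img, labels = sq.make_structural_phantom(spec, 0)
    img = sq.Image3D(
        ndimage.gaussian_filter(img.voxels, 2.0), img.affine, img.voxel_dims
    )
    return img, labels


@pytest.fixture(scope="session")
def icosa_scheme():
    """2 b=0 volumes + 12 icosahedral directions at b=1000 s/mm^2."""
    from scanqa.study import demo_scheme

    return demo_scheme()


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit directions (deterministic Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@pytest.fixture(scope="session")
def scheme60():
    """8 b=0 + 60 directions, the classic DTI protocol shape."""
    dirs = fibonacci_directions(60)
    bvals = np.concatenate([np.zeros(8), np.full(60, 1000.0)])
    bvecs = np.vstack([np.zeros((8, 3)), dirs])
    return sq.DiffusionScheme(bvals, bvecs)
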
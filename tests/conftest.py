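import numpy as np
import pytest

import tumorvol as tv


@pytest.fixture(scope="session")
def fine_sphere():
    """Digitized sphere r=18.8 mm at 0.5 mm isotropic spacing (shared: slow to build)."""
    return tv.make_phantom(tv.ShapeSpec("sphere", radius_mm=18.8, spacing=(0.5, 0.5, 0.5)))


@pytest.fixture(scope="session")
def fine_sphere_features(fine_sphere):
    return tv.extract_features(fine_sphere)


@pytest.fixture()
def box_mask():
    """20x20x20 mm solid box at 1 mm isotropic spacing."""
    return tv.SegmentationMask(np.ones((20, 20, 20), dtype=bool), (1.0, 1.0, 1.0))


@pytest.fixture()
def blob_mask():
    """Irregular connected blob in a <=30^3 grid (union of random balls)."""
    rng = np.random.default_rng(5)
    shape = (26, 24, 22)
    ax = [np.arange(s) for s in shape]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij", sparse=True)
    vox = np.zeros(shape, dtype=bool)
    centers = [(13, 12, 11)] + [tuple(rng.integers(7, s - 7) for s in shape) for _ in range(4)]
    for c in centers:
        r = rng.uniform(4, 7)
        vox |= (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= r**2
    return tv.SegmentationMask(vox, (1.0, 1.2, 1.5))
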
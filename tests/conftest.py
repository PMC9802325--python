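import numpy as np
import pytest

from trabnet import (ExtractionParams, PhantomSpec, Skeleton, SliceImage,
                     generate_slice)

PIXEL = 20.5


@pytest.fixture
def plus_skeleton():
    """Plus-sign skeleton: one center junction, four 6-pixel arms."""
    px = np.zeros((15, 15), bool)
    px[7, 1:14] = True
    px[1:14, 7] = True
    return Skeleton(px, PIXEL)


@pytest.fixture
def line_skeleton():
    """Straight horizontal 11-pixel line."""
    px = np.zeros((5, 15), bool)
    px[2, 2:13] = True
    return Skeleton(px, PIXEL)


@pytest.fixture
def ring_skeleton():
    """Pure 8-connected pixel ring with no junctions."""
    px = np.zeros((12, 12), bool)
    px[2, 3:9] = True
    px[9, 3:9] = True
    px[3:9, 2] = True
    px[3:9, 9] = True
    px[2, 3], px[3, 2] = True, True  # corners already diagonal-connected
    return Skeleton(px, PIXEL)


@pytest.fixture
def thin_phantom():
    """Noiseless thin-strut phantom slice with exact ground truth."""
    spec = PhantomSpec(image_size=256, seed_points=40, strut_thickness_px=1,
                       noise_sigma=0.0, fragmentation_prob=0.1, rng_seed=7)
    return generate_slice(spec, 0)


@pytest.fixture
def clean_extraction():
    """Extraction settings for noiseless binary phantoms."""
    return ExtractionParams(threshold=0.5, min_object_px=0, min_hole_px=0)
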
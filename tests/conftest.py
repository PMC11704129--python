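import numpy as np
import pytest

from persiseg.phantom import PhantomParams, generate_phantom_stack
from persiseg.segmentation import SegmentationConfig, segment_slice_with_info

NOISY_SIGMA = 0.05
NOISY_SEED = 7


@pytest.fixture(scope="session")
def phantom_noiseless():
    """Default phantom stack (blur only, no noise) with its ground truth."""
    return generate_phantom_stack(PhantomParams())


@pytest.fixture(scope="session")
def phantom_noisy():
    import dataclasses

    params = dataclasses.replace(
        PhantomParams(), noise_sigma=NOISY_SIGMA, seed=NOISY_SEED
    )
    return generate_phantom_stack(params)


def _segment_stack(stack):
    cfg = SegmentationConfig()
    return [segment_slice_with_info(im, cfg, k) for k, im in enumerate(stack)]


@pytest.fixture(scope="session")
def segmented_noiseless(phantom_noiseless):
    stack, _ = phantom_noiseless
    return _segment_stack(stack)


@pytest.fixture(scope="session")
def segmented_noisy(phantom_noisy):
    stack, _ = phantom_noisy
    return _segment_stack(stack)


@pytest.fixture(scope="session")
def phantom_mesh(segmented_noiseless):
    from persiseg.reconstruction import ReconstructionConfig, reconstruct_mesh

    segs = [r.segmentation for r in segmented_noiseless]
    return reconstruct_mesh(segs, ReconstructionConfig(), pixel_size=0.16)


@pytest.fixture(scope="session")
def small_phantom_params():
    """A reduced phantom for pipeline-level tests."""
    from persiseg.phantom import CavitySpec, InvaginationSpec, MembraneSpec

    return PhantomParams(
        shape=(64, 96, 6),
        membrane=MembraneSpec(center=(36.0, 48.0), outer_radii=(24.0, 34.0),
                              thickness=4.0),
        invagination=InvaginationSpec(width=8.0, depth=36.0),
        cavities=(CavitySpec(center=(44.0, 36.0, 2.5), radii=(5.0, 5.0, 20.0)),),
        seed=1,
    )


def random_blob_mask(rng, shape=(24, 24)):
    """A random filled 8-connected region for contour round-trip tests."""
    from scipy import ndimage

    while True:
        u = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
        mask = u > np.quantile(u, 0.7)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        if n == 0:
            continue
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
        return ndimage.binary_fill_holes(mask)
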
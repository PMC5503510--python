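import numpy as np
import pytest

from chanprox.locmap import filter_by_photons, rasterize
from chanprox.segmentation import segment
from chanprox.synthetic import SceneSpec, generate_cluster_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_scene():
    """One default clustered scene (association 0.8) shared across tests."""
    spec = SceneSpec(seed=11)
    red, green, truth = generate_cluster_scene(spec)
    return spec, red, green, truth


@pytest.fixture(scope="session")
def segmented_scene(default_scene):
    """Segmented catalogs of the shared scene."""
    spec, red, green, truth = default_scene
    extent = (spec.field_width_nm, spec.field_height_nm)
    red_map = rasterize(filter_by_photons(red), spec.pixel_size_nm,
                        binary=True, extent_nm=extent)
    green_map = rasterize(filter_by_photons(green), spec.pixel_size_nm,
                          binary=True, shape=red_map.shape)
    return segment(red_map), segment(green_map), red_map, green_map, truth


def random_blob_mask(rng, shape, density=0.08, smooth=True):
    """Random sparse binary mask with small connected blobs."""
    from scipy import ndimage as ndi

    g = rng.random(shape) < density
    if smooth:
        g = ndi.binary_dilation(g, np.ones((2, 2)))
    return g
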
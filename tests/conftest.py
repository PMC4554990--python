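import numpy as np
import pytest

from ycnv import defaults, synthetic
from ycnv.haplogroup import load_tree
from ycnv.patterns import load_catalog
from ycnv.probe_map import assign_probes
from ycnv.segmentation import SegmentationParams


@pytest.fixture(scope="session")
def regions():
    return defaults.default_region_map()


@pytest.fixture(scope="session")
def catalog(regions):
    return load_catalog(defaults.default_catalog_path(), regions)


@pytest.fixture(scope="session")
def tree():
    return load_tree(defaults.default_tree_path())


@pytest.fixture(scope="session")
def manifest(regions):
    """Default synthetic manifest (2000-probe scale)."""
    return synthetic.synthetic_manifest(2000, regions=regions)


@pytest.fixture(scope="session")
def manifest_real(regions):
    """Real-scale (8179-probe) synthetic manifest."""
    return synthetic.synthetic_manifest(8179, regions=regions)


@pytest.fixture(scope="session")
def annotation(manifest, regions):
    return assign_probes(manifest, regions)


@pytest.fixture(scope="session")
def annotation_real(manifest_real, regions):
    return assign_probes(manifest_real, regions)


@pytest.fixture(scope="session")
def model():
    return synthetic.IntensityModel()


@pytest.fixture(scope="session")
def seg_params():
    return SegmentationParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
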
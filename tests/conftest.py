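import numpy as np
import pytest

from canopymetrics.structure import measure_tree
from canopymetrics.synthetic import (
    SyntheticTreeSpec,
    generate_tree,
    make_fixture_suite,
)


@pytest.fixture(scope="session")
def default_tree():
    """The reference synthetic tree: 0.40 m DBH, 14 m tall, crown from 3 m,
    2 m cylinder crown, 2 cm spacing, 5 mm noise (study conditions)."""
    spec = SyntheticTreeSpec(seed=1)
    cloud, records, truth = generate_tree(spec)
    return spec, cloud, records, truth


@pytest.fixture(scope="session")
def default_tree_metrics(default_tree):
    _, cloud, records, _ = default_tree
    return measure_tree(cloud, tree_id="default", cylinders=records)


@pytest.fixture(scope="session")
def small_tree():
    """A coarser, faster tree for tests that re-measure several variants."""
    spec = SyntheticTreeSpec(
        seed=7,
        tree_height=8.0,
        crown_start=2.5,
        crown_radius_x=1.5,
        crown_radius_y=1.5,
        point_spacing=0.04,
        noise_sigma=0.003,
        branch_count=4,
    )
    cloud, records, truth = generate_tree(spec)
    return spec, cloud, records, truth


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
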
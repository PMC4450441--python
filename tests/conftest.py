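import warnings

import pytest
from hypothesis import HealthCheck, settings

import rootmosaic as rm

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: compact phantom used by most image-based tests (48 cells, 9 planes)
SMALL_GEOMETRY = dict(n_files=4, cells_per_file=6, n_layers=2)

#: phantom with enough depth structure for the depth-filter tests
DEEP_GEOMETRY = dict(n_files=4, cells_per_file=6, n_layers=4)


@pytest.fixture(scope="session")
def small_geometry():
    return rm.RootGeometry(**SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def demo_root(small_geometry):
    """One bimodal (p_on = 0.5) small synthetic root."""
    stack, truth = rm.generate_root(
        small_geometry, rm.ExpressionModel(p_on=0.5), seed=11
    )
    return stack, truth


@pytest.fixture(scope="session")
def demo_segs(demo_root):
    stack, _ = demo_root
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rm.segment_stack(stack)


@pytest.fixture(scope="session")
def demo_cells(demo_segs):
    return rm.link_planes(demo_segs, rm.LinkCriteria())


@pytest.fixture(scope="session")
def demo_measurements(demo_root, demo_segs, demo_cells):
    stack, _ = demo_root
    return rm.measure_cells(demo_cells, demo_segs, stack)


@pytest.fixture(scope="session")
def demo_pairing(demo_root, demo_segs, demo_cells):
    _, truth = demo_root
    return rm.match_cells(demo_cells, demo_segs, truth)
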
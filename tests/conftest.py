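import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def weibel_tree():
    from mdtsim.lung_geometry import build_weibel_tree

    return build_weibel_tree()


@pytest.fixture(scope="session")
def tumor_tree():
    from mdtsim.lung_geometry import add_tumor, build_weibel_tree

    return add_tumor(build_weibel_tree(), 0.8, "P1", 0.0)


@pytest.fixture(scope="session")
def default_flow(tumor_tree):
    from mdtsim.airflow import solve_flow

    return solve_flow(tumor_tree, 15.0)


@pytest.fixture(scope="session")
def small_magnet():
    """Smallest preset magnet, magnetized; used by field tests."""
    from mdtsim.magnet_field import BulkMagnet, calibrate_jc, magnetize

    a, t = 15e-3, 9e-3
    mag = BulkMagnet(a, t, calibrate_jc(2.11, a, t))
    return mag, magnetize(mag)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
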
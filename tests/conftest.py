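"""Shared fixtures.

The two protocol runs (segmentation suite, density series) take ~15 s each,
so they are computed once per session and shared by all tests that score
them.
"""

import numpy as np
import pytest

from phantast.phantoms import PhantomSpec, generate_phantom
from phantast.suites import run_density_calibration, run_segmentation_suite


@pytest.fixture(scope="session")
def suite_result():
    return run_segmentation_suite(seed=0)


@pytest.fixture(scope="session")
def density_result():
    return run_density_calibration(seed=1)


@pytest.fixture(scope="session")
def small_bundle():
    """One small two-cell phantom used by fast unit tests."""
    spec = PhantomSpec(
        shape=(256, 256),
        n_cells=2,
        radius_range=(20.0, 28.0),
        halo_width_range=(10.0, 15.0),
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
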
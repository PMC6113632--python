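"""Shared fixtures: a small, fast phantom reused across the suite."""

import numpy as np
import pytest

from dtbz.config import (BootstrapConfig, InfarctWedge, LVGeometry,
                         PhantomSpec, RunConfig)
from dtbz.phantom import build_label_geometry, simulate_heart
from dtbz.tensor import AcquisitionScheme


def small_phantom_spec(seed: int = 11, **overrides) -> PhantomSpec:
    """A desk-scale heart: 48x48x10 DTI grid, thin LV annulus, 90-degree
    inferior infarct wedge."""
    kwargs = dict(
        grid_dims_dti=(48, 48, 10),
        lge_upsampling=(3, 3, 9),
        lv_geometry=LVGeometry(inner_radius=10.0, outer_radius=20.0, apex_slice=1),
        infarct_wedge=InfarctWedge(center_angle=-90.0, angular_extent=90.0,
                                   transmural_extent=1.0, slice_range=(2, 7)),
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme.default()


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_labels(small_spec):
    return build_label_geometry(small_spec)


@pytest.fixture(scope="session")
def small_heart(small_spec, scheme):
    return simulate_heart(small_spec, scheme)


@pytest.fixture(scope="session")
def small_run_config():
    return RunConfig(
        n_infarcted=2, n_normal=1,
        phantom=small_phantom_spec(),
        bootstrap=BootstrapConfig(n_resamples_test=1000),
        seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
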
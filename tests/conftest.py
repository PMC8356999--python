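import numpy as np
import pytest

import dntopo as dt


@pytest.fixture(scope="session")
def spec():
    """Default phantom specification (the study conditions)."""
    return dt.PhantomSpec()


@pytest.fixture(scope="session")
def phantom(spec):
    """(mask_left, mask_right, truth_conn, truth_micro) on the default grid."""
    return dt.combined_phantom(spec)


@pytest.fixture(scope="session")
def cohort(spec):
    """The default 25-subject synthetic cohort."""
    return dt.simulate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_grid():
    return dt.default_grid(shape=(10, 10, 10), voxel_mm=1.0)


def make_label_volume(grid, labels, names=None):
    labels = np.asarray(labels, dtype=np.int32)
    if names is None:
        names = {int(l): str(l) for l in np.unique(labels) if l != 0}
    return dt.LabelVolume(grid=grid, labels=labels, label_names=names)
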
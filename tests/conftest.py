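import numpy as np
import pytest

from ctstitch import CoralPhantomSpec, generate_coral_volume


@pytest.fixture(scope="session")
def coral_spec():
    return CoralPhantomSpec(
        z_extent=60, y_extent=48, x_extent=48,
        core_radius_vox=5.0, n_rings=3, ring_period_vox=5.0,
    )


@pytest.fixture(scope="session")
def coral(coral_spec):
    """A small banded coral phantom shared across tests (read-only)."""
    volume, labels = generate_coral_volume(coral_spec, voxel_size_um=15.0)
    volume.voxels.setflags(write=False)
    return volume, labels


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
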
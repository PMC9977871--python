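import numpy as np
import pytest

from tricell.phantoms import PhantomSpec, generate_cell_phantom


@pytest.fixture(scope="session")
def eight_cell_phantom():
    """Clean 8-cell membrane phantom with ground truth (session-cached)."""
    spec = PhantomSpec(volume_shape=(32, 64, 64), n_cells=8, seed=7)
    intensity, labels = generate_cell_phantom(spec)
    return spec, intensity, labels


@pytest.fixture(scope="session")
def quadrant_labels():
    """2x2 quadrant labels in-plane, extruded along z: four cells meeting
    in a central column."""
    labels = np.zeros((4, 8, 8), dtype=np.int32)
    labels[:, :4, :4] = 1
    labels[:, :4, 4:] = 2
    labels[:, 4:, :4] = 3
    labels[:, 4:, 4:] = 4
    return labels


@pytest.fixture(scope="session")
def collinear_labels():
    """Three 3-voxel-wide cells along x with 1-voxel unlabeled gaps."""
    labels = np.zeros((3, 5, 13), dtype=np.int32)
    labels[:, 1:4, 1:4] = 1
    labels[:, 1:4, 5:8] = 2
    labels[:, 1:4, 9:12] = 3
    return labels
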
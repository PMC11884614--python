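import numpy as np
import pytest

from idpcrit.io import Frame, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_bead_frame(points) -> Frame:
    """One-atom-per-residue frame from an (N, 3) point array."""
    points = np.asarray(points, dtype=float)
    return Frame(points, np.arange(len(points)))


def make_bead_trajectory(frames_points, dt=100.0) -> Trajectory:
    return Trajectory([make_bead_frame(p) for p in frames_points], dt=dt)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()
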
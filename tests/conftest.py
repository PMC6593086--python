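import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_traj(rng):
    """60 frames x 8 angles, uniform on the torus."""
    from anglescape import AngleTrajectory

    return AngleTrajectory(rng.uniform(-np.pi, np.pi, size=(60, 8)))


def rigid_rmsd(a, b):
    """RMSD of b onto a after optimal rigid alignment (rotation + reflection
    + translation, no scaling)."""
    from scipy.linalg import orthogonal_procrustes

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    R, _ = orthogonal_procrustes(bc, ac)
    return float(np.sqrt(np.mean(np.sum((bc @ R - ac) ** 2, axis=1))))


def majority_agreement(found, planted):
    """Fraction of frames whose planted label matches the majority planted
    label of their recovered cluster."""
    found = np.asarray(found)
    planted = np.asarray(planted)
    agree = 0
    for m in np.unique(found):
        sel = planted[found == m]
        agree += np.bincount(sel).max()
    return agree / planted.size
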
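import numpy as np
import pytest
from hypothesis import settings

from dcbg import BrushParameters, Trajectory

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params() -> BrushParameters:
    return BrushParameters()


@pytest.fixture
def random_trajectory():
    """Factory for small random trajectories (coords in a ~5 nm box)."""

    def make(n_frames=5, n_res=12, seed=0):
        rng = np.random.default_rng(seed)
        return Trajectory(coords=rng.uniform(-2.5, 2.5, size=(n_frames, n_res, 3)))

    return make


def brute_force_contact_map(traj: Trajectory, cutoff: float) -> np.ndarray:
    """Independent pair-counting oracle: explicit loops, no vectorisation."""
    n = traj.chain_length
    P = np.zeros((n, n))
    for frame in traj.coords:
        for i in range(n):
            for j in range(n):
                d = np.sqrt(((frame[i] - frame[j]) ** 2).sum())
                if d <= cutoff:
                    P[i, j] += 1
    P /= traj.n_frames
    return P
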
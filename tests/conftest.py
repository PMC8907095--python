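import numpy as np
import pytest

from ensdock.synthetic import (
    TrajectorySpec,
    build_toy_protein,
    simulate_markov_trajectory,
)


@pytest.fixture(scope="session")
def toy10():
    """10-residue toy protein and its ligand points."""
    return build_toy_protein(10)


@pytest.fixture(scope="session")
def traj3state():
    """A 3-state Markov trajectory with displacement >> noise (no jitter)."""
    base, ligand = build_toy_protein(24)
    spec = TrajectorySpec(
        n_residues=24,
        n_states=3,
        n_frames=600,
        state_displacement=4.0,
        noise_sigma=0.08,
        rigid_body_jitter=False,
        seed=11,
    )
    traj, states = simulate_markov_trajectory(base, spec)
    return base, ligand, traj, states


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation for invariance tests."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
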
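"""Synthetic data generators: toy proteins, Markov-switching conformational
trajectories, and docking-score matrices with a planted affinity ordering.

Everything is a pure function of its spec plus an integer seed, so every
downstream stage is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError
from .structures import AtomRecord, Trajectory

__all__ = [
    "TrajectorySpec",
    "ScoreSpec",
    "build_toy_protein",
    "binding_loop_residues",
    "binding_loop_atom_indices",
    "simulate_markov_trajectory",
    "simulate_score_matrix",
    "simulate_experimental_affinities",
    "stationary_distribution",
]

_BACKBONE_OFFSETS = {
    # local offsets (Å) of the four backbone atoms within a residue
    "N": np.array([-0.7, -0.6, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.8, 0.5, 0.2]),
    "O": np.array([0.9, 1.6, 0.4]),
}


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a Markov-switching conformational trajectory."""

    n_residues: int = 20
    n_states: int = 3
    n_frames: int = 1000
    transition_matrix: np.ndarray | None = None
    state_displacement: float = 3.0
    noise_sigma: float = 0.1
    rigid_body_jitter: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_states < 1:
            raise InvalidSpecError("n_states must be >= 1")
        if self.n_frames < 1:
            raise InvalidSpecError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        T = self.transition_matrix
        if T is None:
            # default: sticky symmetric chain
            stay = 0.95
            T = np.full((self.n_states, self.n_states),
                        (1 - stay) / max(self.n_states - 1, 1))
            np.fill_diagonal(T, stay if self.n_states > 1 else 1.0)
        T = np.asarray(T, dtype=float)
        if T.shape != (self.n_states, self.n_states):
            raise InvalidSpecError(
                f"transition_matrix shape {T.shape} != "
                f"({self.n_states}, {self.n_states})"
            )
        if np.any(T < 0):
            raise InvalidSpecError("transition_matrix entries must be >= 0")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise InvalidSpecError("transition_matrix rows must sum to 1")
        object.__setattr__(self, "transition_matrix", T)


@dataclass(frozen=True)
class ScoreSpec:
    """Parameters of a planted-affinity docking score matrix.

    Scores follow s(l, i) = a_l + b_i + c_{l,i} + eps with a_l uniform on
    ``affinity_range`` (lower = tighter binder), b_i a per-conformation bias,
    c a ligand x conformation compatibility term, and eps iid noise.
    """

    n_ligands: int = 50
    n_conformations: int = 10
    affinity_range: tuple[float, float] = (-10.0, -4.0)
    conformation_bias_sigma: float = 0.0
    compatibility_sigma: float = 0.0
    noise_sigma: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ligands < 1 or self.n_conformations < 1:
            raise InvalidSpecError("need >= 1 ligand and >= 1 conformation")
        if not 0 <= self.missing_fraction < 1:
            raise InvalidSpecError("missing_fraction must be in [0, 1)")
        lo, hi = self.affinity_range
        if not lo < hi:
            raise InvalidSpecError("affinity_range must be a nonempty interval")
        for name in ("conformation_bias_sigma", "compatibility_sigma",
                     "noise_sigma"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")


def binding_loop_residues(n_residues: int) -> np.ndarray:
    """1-based residue numbers of the designated binding loop (middle third)."""
    lo = n_residues // 3
    hi = max(lo + 1, (2 * n_residues) // 3)
    return np.arange(lo + 1, hi + 1)


def binding_loop_atom_indices(traj: Trajectory) -> np.ndarray:
    """0-based atom indices belonging to the binding-loop residues."""
    n_res = max(r.residue_number for r in traj.topology)
    loop = set(binding_loop_residues(n_res).tolist())
    return np.array(
        [r.atom_index for r in traj.topology if r.residue_number in loop],
        dtype=int,
    )


def build_toy_protein(n_residues: int):
    """A one-frame toy structure (4 backbone atoms per residue on a helix-like
    curve) plus a small ligand point set adjacent to the binding loop.

    Returns (Trajectory with one frame, ligand_coords L x 3).
    """
    if n_residues < 3:
        raise InvalidSpecError("n_residues must be >= 3")
    records = []
    coords = []
    rise, radius, turn = 1.6, 4.0, 0.7
    for r in range(n_residues):
        theta = turn * r
        ca = np.array(
            [radius * np.cos(theta), radius * np.sin(theta), rise * r]
        )
        for name in ("N", "CA", "C", "O"):
            records.append(
                AtomRecord(
                    atom_index=len(records),
                    atom_name=name,
                    residue_number=r + 1,
                    residue_name="ALA",
                    chain_id="A",
                    element=name[0],
                )
            )
            coords.append(ca + _BACKBONE_OFFSETS[name])
    traj = Trajectory(tuple(records), np.array(coords))

    # ligand: an elongated chain hugging up to three consecutive binding-loop
    # residues (1.5 Å radially off each CA), so the binding-atoms selection
    # spans several residues
    loop = binding_loop_residues(n_residues)
    mid = len(loop) // 2
    contact_res = [int(loop[i]) for i in (mid - 1, mid, mid + 1)
                   if 0 <= i < len(loop)]
    ligand_pts = []
    for resnum in contact_res:
        ca_idx = next(
            r.atom_index
            for r in records
            if r.residue_number == resnum and r.atom_name == "CA"
        )
        anchor = traj.coordinates[0, ca_idx]
        outward = anchor - np.array([0.0, 0.0, anchor[2]])
        outward /= np.linalg.norm(outward)
        base = anchor + 1.5 * outward
        ligand_pts.append(base)
        ligand_pts.append(base + 0.7 * outward)
    return traj, np.array(ligand_pts)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized."""
    evals, evecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def simulate_markov_trajectory(base: Trajectory, spec: TrajectorySpec):
    """Markov-switching trajectory around a base structure.

    Frame t = base + state displacement of the binding-loop atoms + isotropic
    Gaussian jitter, optionally followed by a random rigid-body transform.
    The chain starts from its stationary distribution.  Returns
    (Trajectory, true_state_labels).
    """
    rng = np.random.default_rng(spec.seed)
    base_xyz = base.coordinates[0]
    loop_idx = binding_loop_atom_indices(base)
    if loop_idx.size == 0:
        raise InvalidSpecError("binding-loop displacement subset is empty")

    T = spec.transition_matrix
    pi = stationary_distribution(T)
    states = np.empty(spec.n_frames, dtype=int)
    states[0] = rng.choice(spec.n_states, p=pi)
    for t in range(1, spec.n_frames):
        states[t] = rng.choice(spec.n_states, p=T[states[t - 1]])

    # per-(state, loop-residue) displacement directions so each state is an
    # internal deformation of the loop, not a rigid shift a superposition
    # could cancel (deterministic sub-stream: coordinates depend only on
    # spec + seed)
    loop_resnums = sorted({base.topology[i].residue_number for i in loop_idx})
    res_of_loop_atom = np.array(
        [loop_resnums.index(base.topology[i].residue_number) for i in loop_idx]
    )
    dir_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    directions = dir_rng.standard_normal((spec.n_states, len(loop_resnums), 3))
    directions /= np.linalg.norm(directions, axis=2, keepdims=True)

    coords = np.repeat(base_xyz[None, :, :], spec.n_frames, axis=0)
    for s in range(spec.n_states):
        mask = states == s
        disp = spec.state_displacement * directions[s][res_of_loop_atom]
        coords[np.ix_(mask, loop_idx)] += disp
    coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    if spec.rigid_body_jitter:
        jit_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
        for t in range(spec.n_frames):
            R = _random_rotation(jit_rng)
            shift = jit_rng.uniform(-5.0, 5.0, size=3)
            coords[t] = coords[t] @ R.T + shift

    traj = Trajectory(base.topology, coords, base.frame_spacing)
    return traj, states


def simulate_score_matrix(spec: ScoreSpec):
    """Planted-affinity score matrix.

    Returns (ScoreMatrix, true_affinity) where true_affinity is the planted
    per-ligand a_l (lower = better).  Missing cells are NaN in the matrix's
    masked representation, never a numeric placeholder.
    """
    from .ranking import ScoreMatrix

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.affinity_range
    a = rng.uniform(lo, hi, size=spec.n_ligands)
    b = rng.normal(0.0, spec.conformation_bias_sigma, size=spec.n_conformations)
    c = rng.normal(
        0.0, spec.compatibility_sigma,
        size=(spec.n_ligands, spec.n_conformations),
    )
    eps = rng.normal(
        0.0, spec.noise_sigma, size=(spec.n_ligands, spec.n_conformations)
    )
    scores = a[:, None] + b[None, :] + c + eps

    mask = np.zeros(scores.shape, dtype=bool)
    if spec.missing_fraction > 0:
        n_cells = scores.size
        n_missing = int(round(spec.missing_fraction * n_cells))
        flat = rng.choice(n_cells, size=n_missing, replace=False)
        mask.flat[flat] = True

    ligand_ids = [f"L{i + 1:03d}" for i in range(spec.n_ligands)]
    conf_ids = [f"conf_{j}" for j in range(spec.n_conformations)]
    sm = ScoreMatrix(ligand_ids, conf_ids, scores, missing=mask)
    return sm, a


def simulate_experimental_affinities(
    true_affinity: np.ndarray,
    noise_sigma: float,
    seed: int = 0,
    scale: float = 1.0,
    ligand_ids: list[str] | None = None,
):
    """Noisy pseudo-experimental pIC50 table.

    pIC50_l = -true_affinity_l * scale + N(0, noise_sigma^2), so the planted
    best binder (lowest score) gets the highest pIC50.
    """
    from .ranking import AffinityTable

    a = np.asarray(true_affinity, dtype=float)
    if a.size == 0:
        raise InvalidSpecError("true_affinity must be non-empty")
    rng = np.random.default_rng(seed)
    pic50 = -a * scale + rng.normal(0.0, noise_sigma, size=a.shape)
    if ligand_ids is None:
        ligand_ids = [f"L{i + 1:03d}" for i in range(a.size)]
    return AffinityTable(ligand_ids, pic50)
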
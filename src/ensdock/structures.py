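"""Trajectory data model, multi-model PDB I/O, atom selections, and
superposition-based ensemble diagnostics (pairwise RMSD, RMSF).

Coordinates are in Å throughout.  Residue numbers are 1-based (PDB
convention); atom indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    EmptySelectionError,
    FormatError,
    GeometryError,
    InvalidArgumentError,
    TopologyError,
)

BACKBONE_NAMES = ("N", "CA", "C", "O")

__all__ = [
    "AtomRecord",
    "Trajectory",
    "AtomSelection",
    "EnsembleDiagnostics",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atoms",
    "select_binding_atoms",
    "kabsch_rotation",
    "kabsch_superpose",
    "pairwise_rmsd",
    "pairwise_rmsd_matrix",
    "rmsf",
    "featurize_positions",
    "subsample",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology."""

    atom_index: int
    atom_name: str
    residue_number: int
    residue_name: str
    chain_id: str
    element: str


@dataclass
class Trajectory:
    """An ordered list of atoms plus an F x A x 3 coordinate block."""

    topology: tuple[AtomRecord, ...]
    coordinates: np.ndarray
    frame_spacing: float = 1.0

    def __post_init__(self):
        self.topology = tuple(self.topology)
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise InvalidArgumentError(
                f"coordinates must be F x A x 3, got shape {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise InvalidArgumentError("trajectory needs at least one frame")
        if coords.shape[1] != len(self.topology):
            raise TopologyError(
                f"coordinate atom count {coords.shape[1]} does not match "
                f"topology length {len(self.topology)}"
            )
        if not np.all(np.isfinite(coords)):
            raise InvalidArgumentError("coordinates must be finite")
        for i, rec in enumerate(self.topology):
            if rec.atom_index != i:
                raise TopologyError(
                    f"atom_index {rec.atom_index} at position {i}: indices "
                    "must be contiguous from 0"
                )
        self.coordinates = coords

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> "Trajectory":
        """Single-frame view (copy) of frame ``i``."""
        return Trajectory(self.topology, self.coordinates[i].copy(),
                          self.frame_spacing)

    def same_topology(self, other: "Trajectory") -> bool:
        return self.topology == other.topology


@dataclass(frozen=True)
class AtomSelection:
    """Ordered 0-based atom-index subset with a provenance label."""

    indices: np.ndarray
    label: str = "custom"

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise InvalidArgumentError("selection indices must be 1-D")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise InvalidArgumentError("selection indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise InvalidArgumentError("selection indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate(self, traj: Trajectory) -> None:
        if self.indices.size and self.indices[-1] >= traj.n_atoms:
            raise InvalidArgumentError(
                f"selection index {self.indices[-1]} out of range for "
                f"{traj.n_atoms} atoms"
            )

    def to_text(self) -> str:
        return " ".join(str(i) for i in self.indices)

    @classmethod
    def from_text(cls, text: str, label: str = "custom") -> "AtomSelection":
        return cls(np.array([int(t) for t in text.split()], dtype=int), label)


@dataclass
class EnsembleDiagnostics:
    """Pairwise RMSD matrix and per-atom RMSF for a set of structures."""

    pairwise_rmsd: np.ndarray
    rmsf: np.ndarray
    structure_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/HETATM, MODEL/ENDMDL)
# ---------------------------------------------------------------------------

def _format_atom_name(name: str) -> str:
    # Names of <4 chars start in column 14 per the PDB convention.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_line(serial: int, rec: AtomRecord, xyz: np.ndarray) -> str:
    return (
        f"ATOM  {serial:5d} {_format_atom_name(rec.atom_name)} "
        f"{rec.residue_name:<3s} {rec.chain_id:1s}{rec.residue_number:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {rec.element:>2s}"
    )


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write every frame as a MODEL/ENDMDL block (single frame: bare block)."""
    path = Path(path)
    lines: list[str] = []
    multi = traj.n_frames > 1
    for f in range(traj.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        for a, rec in enumerate(traj.topology):
            lines.append(_atom_line(a + 1, rec, traj.coordinates[f, a]))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray]:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resnum = int(line[22:26])
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = name[:1]
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable ATOM record at line {lineno}: {exc}")
    rec = AtomRecord(0, name, resnum, resname, chain, element)
    return rec, xyz


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    Models must all contain the same atoms; a bare coordinate block without
    MODEL records yields a single frame.
    """
    path = Path(path)
    frames: list[list[np.ndarray]] = []
    topologies: list[list[AtomRecord]] = []
    current_coords: list[np.ndarray] | None = None
    current_topo: list[AtomRecord] | None = None
    model_no = 0
    saw_model = False

    def close_model():
        nonlocal current_coords, current_topo
        if current_coords:
            frames.append(current_coords)
            topologies.append(current_topo)
        current_coords, current_topo = None, None

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            saw_model = True
            close_model()
            model_no += 1
            current_coords, current_topo = [], []
        elif record == "ENDMDL":
            close_model()
        elif record in ("ATOM", "HETATM"):
            if current_coords is None:
                current_coords, current_topo = [], []
                if not saw_model:
                    model_no = 1
            rec, xyz = _parse_atom_line(line, lineno)
            current_topo.append(replace(rec, atom_index=len(current_topo)))
            current_coords.append(xyz)
    close_model()

    if not frames:
        raise FormatError(f"{path}: no ATOM records found")

    n_atoms = len(frames[0])
    for m, fr in enumerate(frames, start=1):
        if len(fr) != n_atoms:
            raise FormatError(
                f"{path}: model {m} has {len(fr)} atoms, expected {n_atoms}"
            )
        if topologies[m - 1] != topologies[0]:
            raise FormatError(
                f"{path}: model {m} atom metadata differs from model 1"
            )

    coords = np.array(frames, dtype=float)
    return Trajectory(tuple(topologies[0]), coords)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_atoms(traj: Trajectory, mode: str) -> AtomSelection:
    """Select atoms by name: ``backbone`` (N, CA, C, O) or ``c-alpha`` (CA)."""
    if mode == "backbone":
        wanted = set(BACKBONE_NAMES)
    elif mode == "c-alpha":
        wanted = {"CA"}
    else:
        raise InvalidArgumentError(f"unknown selection mode {mode!r}")
    idx = np.array(
        [r.atom_index for r in traj.topology if r.atom_name in wanted],
        dtype=int,
    )
    if idx.size == 0:
        raise EmptySelectionError(f"selection {mode!r} matched no atoms")
    return AtomSelection(idx, mode)


def select_binding_atoms(
    structure: Trajectory,
    ligand_poses: np.ndarray,
    cutoff: float = 2.0,
) -> AtomSelection:
    """Receptor atoms within ``cutoff`` Å (inclusive) of any ligand atom in
    any pose; the union over poses."""
    poses = np.asarray(ligand_poses, dtype=float)
    if poses.ndim == 2:
        poses = poses[None, :, :]
    if poses.ndim != 3 or poses.shape[0] < 1:
        raise InvalidArgumentError("ligand_poses must be P x L x 3 with P >= 1")
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be positive")
    receptor = structure.coordinates[0]
    lig = poses.reshape(-1, 3)
    mind = cdist(receptor, lig).min(axis=1)
    idx = np.nonzero(mind <= cutoff)[0]
    if idx.size == 0:
        raise EmptySelectionError(
            "no receptor atoms within the cutoff of the ligand poses"
        )
    return AtomSelection(idx.astype(int), "binding-atoms")


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_rotation(ref: np.ndarray, mob: np.ndarray) -> np.ndarray:
    """Proper rotation (det = +1) minimizing RMSD of centered ``mob`` onto
    centered ``ref``."""
    H = mob.T @ ref
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return (U @ D @ Vt).T


def _check_fit_coords(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise GeometryError("need at least 3 fit atoms for superposition")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise GeometryError("fit atoms are collinear or coincident")


def kabsch_superpose(
    reference: np.ndarray,
    mobile: np.ndarray,
    fit_selection: AtomSelection | np.ndarray | None = None,
):
    """Superpose ``mobile`` onto ``reference`` over the fit atoms.

    Returns the transformed full ``mobile`` coordinates and the RMSD computed
    over the fit selection after optimal superposition.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape:
        raise TopologyError(
            f"reference {ref.shape} and mobile {mob.shape} shapes differ"
        )
    if fit_selection is None:
        idx = np.arange(ref.shape[0])
    elif isinstance(fit_selection, AtomSelection):
        idx = fit_selection.indices
    else:
        idx = np.asarray(fit_selection, dtype=int)
    ref_fit, mob_fit = ref[idx], mob[idx]
    _check_fit_coords(ref_fit)
    _check_fit_coords(mob_fit)

    ref_c = ref_fit.mean(axis=0)
    mob_c = mob_fit.mean(axis=0)
    R = kabsch_rotation(ref_fit - ref_c, mob_fit - mob_c)
    transformed = (mob - mob_c) @ R.T + ref_c
    diff = transformed[idx] - ref_fit
    rmsd = float(np.sqrt((diff ** 2).sum() / idx.size))
    return transformed, rmsd


def _batched_pairwise_rmsd(X: np.ndarray) -> np.ndarray:
    """All-vs-all Kabsch RMSD for an S x A x 3 stack (single batched SVD)."""
    S, A, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    sq = np.einsum("sak,sak->s", Xc, Xc)
    # Cross-covariance of every ordered pair, then batched 3x3 SVD.
    H = np.einsum("iak,jal->ijkl", Xc, Xc)
    U, sv, Vt = np.linalg.svd(H.reshape(S * S, 3, 3))
    det = np.linalg.det(np.einsum("nij,njk->nik", U, Vt))
    sv[:, 2] *= np.sign(det)
    tr = sv.sum(axis=1).reshape(S, S)
    msd = (sq[:, None] + sq[None, :] - 2.0 * tr) / A
    D = np.sqrt(np.maximum(msd, 0.0))
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def pairwise_rmsd_matrix(
    coords: np.ndarray, selection: AtomSelection | np.ndarray | None = None
) -> np.ndarray:
    """Symmetric Kabsch-RMSD matrix over an F x A x 3 coordinate stack."""
    X = np.asarray(coords, dtype=float)
    if selection is not None:
        idx = (
            selection.indices
            if isinstance(selection, AtomSelection)
            else np.asarray(selection, dtype=int)
        )
        X = X[:, idx, :]
    if X.shape[1] < 3:
        raise GeometryError("need at least 3 atoms for pairwise RMSD")
    return _batched_pairwise_rmsd(X)


def _stack_structures(structures: Sequence[Trajectory]) -> np.ndarray:
    if len(structures) < 2:
        raise InvalidArgumentError("need at least 2 structures")
    topo = structures[0].topology
    for i, s in enumerate(structures):
        if s.topology != topo:
            raise TopologyError(f"structure {i} topology differs from structure 0")
    return np.stack([s.coordinates[0] for s in structures])


def pairwise_rmsd(
    structures: Sequence[Trajectory],
    selection: AtomSelection,
    ids: Iterable[str] | None = None,
) -> EnsembleDiagnostics:
    """Pairwise Kabsch RMSD over ``selection`` for a list of single frames."""
    X = _stack_structures(structures)
    D = pairwise_rmsd_matrix(X, selection)
    labels = list(ids) if ids is not None else [f"s{i}" for i in range(len(structures))]
    return EnsembleDiagnostics(D, np.array([]), labels)


def rmsf(
    structures: Sequence[Trajectory], selection: AtomSelection
) -> np.ndarray:
    """Per-atom RMSF about the ensemble mean, fitting on ``selection``.

    Each structure is first superposed onto structure 0 over the selection;
    the resulting mean structure then serves as the final fit reference
    (one refinement pass).
    """
    X = _stack_structures(structures)
    idx = selection.indices

    def _align_all(stack, ref):
        out = np.empty_like(stack)
        for i in range(stack.shape[0]):
            out[i], _ = kabsch_superpose(ref, stack[i], idx)
        return out

    aligned = _align_all(X, X[0])
    mean = aligned.mean(axis=0)
    aligned = _align_all(aligned, mean)
    mean = aligned.mean(axis=0)
    dev = aligned - mean
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))


def featurize_positions(
    traj: Trajectory,
    selection: AtomSelection,
    reference_frame: int = 0,
):
    """Flattened, superposed position features: F x 3|selection|.

    Every frame is Kabsch-superposed onto ``reference_frame`` over the
    selection before the selected coordinates are flattened, so rigid-body
    motion does not leak into the features.
    """
    from .dimred import FeatureMatrix

    if len(selection) == 0:
        raise EmptySelectionError("cannot featurize an empty selection")
    selection.validate(traj)
    idx = selection.indices
    ref = traj.coordinates[reference_frame]
    F = traj.n_frames
    out = np.empty((F, idx.size * 3))
    for f in range(F):
        aligned, _ = kabsch_superpose(ref, traj.coordinates[f], idx)
        out[f] = aligned[idx].ravel()
    labels = [
        f"{traj.topology[a].atom_name}{traj.topology[a].residue_number}.{c}"
        for a in idx
        for c in "xyz"
    ]
    return FeatureMatrix(out, labels, traj.frame_spacing)


def subsample(traj: Trajectory, stride: int) -> Trajectory:
    """Keep frames 0, stride, 2*stride, ...; frame spacing scales by stride."""
    if stride < 1:
        raise InvalidArgumentError("stride must be >= 1")
    return Trajectory(
        traj.topology,
        traj.coordinates[::stride].copy(),
        traj.frame_spacing * stride,
    )
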
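import numpy as np
import pytest

from ensdock.errors import (
    EmptySelectionError,
    FormatError,
    GeometryError,
    InvalidArgumentError,
    TopologyError,
)
from ensdock.structures import (
    AtomSelection,
    Trajectory,
    featurize_positions,
    kabsch_superpose,
    pairwise_rmsd,
    pairwise_rmsd_matrix,
    read_multimodel_pdb,
    rmsf,
    select_atoms,
    select_binding_atoms,
    subsample,
    write_multimodel_pdb,
)
from ensdock.synthetic import TrajectorySpec, build_toy_protein, simulate_markov_trajectory

from conftest import random_rotation


# ---------------------------------------------------------------------------
# rotation-search oracle for Kabsch (independent of the SVD route)
# ---------------------------------------------------------------------------

def _rotations_from_quats(Q):
    Q = Q / np.linalg.norm(Q, axis=1, keepdims=True)
    w, x, y, z = Q.T
    R = np.empty((len(Q), 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def rmsd_search_oracle(ref, mob, n_coarse=20000, n_refine=6, seed=0):
    """Best RMSD over random quaternion search with local refinement."""
    rng = np.random.default_rng(seed)
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)

    def batch_rmsd(R):
        moved = np.einsum("nij,aj->nai", R, mob_c)
        return np.sqrt(((moved - ref_c) ** 2).sum(axis=(1, 2)) / ref.shape[0])

    best_q = None
    best = np.inf
    Q = rng.standard_normal((n_coarse, 4))
    r = batch_rmsd(_rotations_from_quats(Q))
    i = r.argmin()
    best, best_q = r[i], Q[i] / np.linalg.norm(Q[i])
    scale = 0.3
    for _ in range(n_refine):
        Q = best_q + scale * rng.standard_normal((5000, 4))
        r = batch_rmsd(_rotations_from_quats(Q))
        i = r.argmin()
        if r[i] < best:
            best, best_q = r[i], Q[i] / np.linalg.norm(Q[i])
        scale *= 0.25
    return float(best)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

class TestPdbIO:
    def test_roundtrip_coordinates(self, toy10, tmp_path):
        base, _ = toy10
        rng = np.random.default_rng(0)
        coords = np.stack([base.coordinates[0] + rng.normal(0, 1, base.coordinates[0].shape)
                           for _ in range(3)])
        traj = Trajectory(base.topology, coords)
        p = tmp_path / "t.pdb"
        write_multimodel_pdb(traj, p)
        back = read_multimodel_pdb(p)
        assert back.n_frames == 3
        assert np.allclose(back.coordinates, traj.coordinates, atol=1e-3)
        assert back.topology == traj.topology

    def test_write_read_write_byte_stable(self, toy10, tmp_path):
        base, _ = toy10
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_multimodel_pdb(base, p1)
        write_multimodel_pdb(read_multimodel_pdb(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_atom_in_model_cites_model(self, toy10, tmp_path):
        base, _ = toy10
        coords = np.repeat(base.coordinates, 3, axis=0)
        traj = Trajectory(base.topology, coords)
        p = tmp_path / "bad.pdb"
        write_multimodel_pdb(traj, p)
        lines = p.read_text().splitlines()
        # remove the first ATOM line inside MODEL 2
        start = lines.index("MODEL        2")
        del lines[start + 1]
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="model 2"):
            read_multimodel_pdb(p)

    def test_unparseable_atom_line_reports_lineno(self, toy10, tmp_path):
        base, _ = toy10
        p = tmp_path / "bad.pdb"
        write_multimodel_pdb(base, p)
        lines = p.read_text().splitlines()
        lines[4] = lines[4][:30] + "  xxxxxx" + lines[4][38:]
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="line 5"):
            read_multimodel_pdb(p)

    def test_bare_block_single_frame(self, toy10, tmp_path):
        base, _ = toy10
        p = tmp_path / "single.pdb"
        write_multimodel_pdb(base, p)  # single frame -> no MODEL records
        assert "MODEL" not in p.read_text()
        assert read_multimodel_pdb(p).n_frames == 1


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

class TestSelections:
    def test_backbone_four_per_residue(self, toy10):
        base, _ = toy10
        assert len(select_atoms(base, "backbone")) == 40

    def test_calpha_one_per_residue(self, toy10):
        base, _ = toy10
        sel = select_atoms(base, "c-alpha")
        assert len(sel) == 10
        assert all(base.topology[i].atom_name == "CA" for i in sel.indices)

    def test_no_match_raises(self, toy10):
        base, _ = toy10
        from dataclasses import replace
        topo = tuple(replace(r, atom_name="X") for r in base.topology)
        t = Trajectory(topo, base.coordinates)
        with pytest.raises(EmptySelectionError):
            select_atoms(t, "c-alpha")

    def _line_structure(self):
        from ensdock.structures import AtomRecord
        topo = tuple(AtomRecord(i, "CA", i + 1, "ALA", "A", "C") for i in range(3))
        coords = np.array([[1.9, 0, 0], [2.1, 0, 0], [50.0, 0, 0]])
        return Trajectory(topo, coords)

    def test_cutoff_excludes_beyond(self):
        t = self._line_structure()
        sel = select_binding_atoms(t, np.zeros((1, 1, 3)), cutoff=2.0)
        assert sel.indices.tolist() == [0]
        assert sel.label == "binding-atoms"

    def test_cutoff_inclusive_boundary(self):
        from ensdock.structures import AtomRecord
        topo = (AtomRecord(0, "CA", 1, "ALA", "A", "C"),)
        t = Trajectory(topo, np.array([[2.0, 0.0, 0.0]]))
        sel = select_binding_atoms(t, np.zeros((1, 1, 3)), cutoff=2.0)
        assert sel.indices.tolist() == [0]

    def test_union_over_poses(self):
        t = self._line_structure()
        poses = np.array([[[1.0, 0, 0]], [[49.5, 0, 0]]])
        sel = select_binding_atoms(t, poses, cutoff=2.0)
        # brute-force union oracle
        expected = set()
        for p in poses:
            for i, xyz in enumerate(t.coordinates[0]):
                if np.linalg.norm(xyz - p[0]) <= 2.0:
                    expected.add(i)
        assert set(sel.indices.tolist()) == expected

    def test_far_ligand_raises(self):
        t = self._line_structure()
        with pytest.raises(EmptySelectionError):
            select_binding_atoms(t, np.full((1, 1, 3), 500.0), cutoff=2.0)

    def test_selection_text_roundtrip(self):
        sel = AtomSelection(np.array([1, 5, 9]), "custom")
        assert AtomSelection.from_text(sel.to_text()).indices.tolist() == [1, 5, 9]


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

class TestKabsch:
    def _cloud(self, n=5, seed=2):
        return np.random.default_rng(seed).normal(0, 2, (n, 3))

    def test_identity(self):
        x = self._cloud()
        _, r = kabsch_superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_translation_invariance(self):
        x = self._cloud()
        _, r = kabsch_superpose(x, x + np.array([5.0, -3.0, 2.0]))
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_rotation_search_oracle(self):
        x = self._cloud()
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        y = x @ Rz.T
        y[0] += np.array([1.0, 0, 0])
        _, r = kabsch_superpose(x, y)
        oracle = rmsd_search_oracle(x, y)
        assert abs(r - oracle) < 1e-3
        assert r <= oracle + 1e-9  # Kabsch is the global optimum

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_small(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 6)
        x = rng.normal(0, 2, (n, 3))
        while np.linalg.svd(x - x.mean(0), compute_uv=False)[1] < 0.3:
            x = rng.normal(0, 2, (n, 3))
        y = x @ random_rotation(rng).T + rng.normal(0, 0.3, (n, 3))
        _, r = kabsch_superpose(x, y)
        assert abs(r - rmsd_search_oracle(x, y, seed=seed)) < 1e-3

    def test_proper_rotation_on_mirror_input(self):
        x = self._cloud(6)
        y = x.copy()
        y[:, 0] = -y[:, 0]  # improper transform; result must stay proper
        moved, _ = kabsch_superpose(x, y)
        from ensdock.structures import kabsch_rotation
        R = kabsch_rotation(x - x.mean(0), y - y.mean(0))
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_atoms(self):
        x = self._cloud(2)
        with pytest.raises(GeometryError):
            kabsch_superpose(x, x)

    def test_collinear_atoms(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_superpose(x, x)


# ---------------------------------------------------------------------------
# pairwise RMSD / RMSF / featurization
# ---------------------------------------------------------------------------

def _frames_from(base, displacements):
    return [
        Trajectory(base.topology, base.coordinates[0] + d) for d in displacements
    ]


class TestDiagnostics:
    def test_duplicates_zero_matrix(self, toy10):
        base, _ = toy10
        sel = select_atoms(base, "c-alpha")
        d = pairwise_rmsd([base, base, base], sel)
        assert np.allclose(d.pairwise_rmsd, 0.0, atol=1e-8)

    def test_matches_per_pair_kabsch(self, toy10):
        base, _ = toy10
        rng = np.random.default_rng(4)
        structs = _frames_from(base, [rng.normal(0, 0.5, base.coordinates[0].shape)
                                      for _ in range(3)])
        sel = select_atoms(base, "backbone")
        D = pairwise_rmsd(structs, sel).pairwise_rmsd
        for i in range(3):
            for j in range(3):
                _, r = kabsch_superpose(
                    structs[i].coordinates[0][sel.indices],
                    structs[j].coordinates[0][sel.indices],
                )
                assert D[i, j] == pytest.approx(r, abs=1e-8)
        assert np.allclose(D, D.T, atol=1e-8)
        assert np.allclose(np.diag(D), 0.0, atol=1e-8)

    def test_global_rotation_invariance(self, toy10):
        base, _ = toy10
        rng = np.random.default_rng(5)
        structs = _frames_from(base, [rng.normal(0, 0.5, base.coordinates[0].shape)
                                      for _ in range(4)])
        sel = select_atoms(base, "c-alpha")
        D1 = pairwise_rmsd(structs, sel).pairwise_rmsd
        rotated = []
        for s in structs:
            R = random_rotation(rng)
            rotated.append(Trajectory(s.topology, s.coordinates[0] @ R.T + rng.normal(0, 5, 3)))
        D2 = pairwise_rmsd(rotated, sel).pairwise_rmsd
        assert np.allclose(D1, D2, atol=1e-6)

    def test_topology_mismatch(self, toy10):
        base, _ = toy10
        other, _ = build_toy_protein(11)
        with pytest.raises(TopologyError):
            pairwise_rmsd([base, other.frame(0)], select_atoms(base, "c-alpha"))

    def test_rmsf_identical_structures(self, toy10):
        base, _ = toy10
        sel = select_atoms(base, "c-alpha")
        assert np.allclose(rmsf([base, base, base], sel), 0.0, atol=1e-10)

    def test_rmsf_single_displaced_atom(self, toy10):
        base, _ = toy10
        d = 0.8
        shift = np.zeros(base.coordinates[0].shape)
        shift[38] = [d, 0, 0]  # a non-CA atom, outside the c-alpha fit set
        structs = _frames_from(base, [np.zeros_like(shift), shift])
        sel = select_atoms(base, "c-alpha")
        assert 38 not in sel.indices
        vals = rmsf(structs, sel)
        assert vals[38] == pytest.approx(d / 2, abs=1e-8)
        mask = np.ones(len(vals), dtype=bool)
        mask[38] = False
        assert np.allclose(vals[mask], 0.0, atol=1e-8)

    def test_rmsf_rotation_invariant(self, toy10):
        base, _ = toy10
        rng = np.random.default_rng(6)
        structs = _frames_from(base, [rng.normal(0, 0.3, base.coordinates[0].shape)
                                      for _ in range(4)])
        sel = select_atoms(base, "backbone")
        v1 = rmsf(structs, sel)
        R = random_rotation(rng)
        rotated = [Trajectory(s.topology, s.coordinates[0] @ R.T) for s in structs]
        assert np.allclose(v1, rmsf(rotated, sel), atol=1e-6)


class TestFeaturize:
    def test_rigid_motion_gives_constant_rows(self, toy10):
        base, _ = toy10
        rng = np.random.default_rng(7)
        frames = []
        for _ in range(5):
            R = random_rotation(rng)
            frames.append(base.coordinates[0] @ R.T + rng.uniform(-4, 4, 3))
        traj = Trajectory(base.topology, np.stack(frames))
        X = featurize_positions(traj, select_atoms(base, "backbone"))
        assert np.allclose(X.values - X.values[0], 0.0, atol=1e-8)

    def test_shape(self, traj3state):
        _, _, traj, _ = traj3state
        sel = select_atoms(traj, "c-alpha")
        sub = subsample(traj, 120)
        X = featurize_positions(sub, sel)
        assert X.values.shape == (sub.n_frames, 3 * len(sel))

    def test_column_means_equal_mean_structure(self, toy10):
        base, _ = toy10
        rng = np.random.default_rng(8)
        coords = np.stack([base.coordinates[0] + rng.normal(0, 0.2, base.coordinates[0].shape)
                           for _ in range(6)])
        traj = Trajectory(base.topology, coords)
        sel = select_atoms(base, "backbone")
        X = featurize_positions(traj, sel)
        aligned = []
        for f in range(6):
            m, _ = kabsch_superpose(coords[0], coords[f], sel.indices)
            aligned.append(m[sel.indices].ravel())
        assert np.allclose(X.values.mean(axis=0), np.mean(aligned, axis=0), atol=1e-10)

    def test_empty_selection(self, toy10):
        base, _ = toy10
        with pytest.raises(EmptySelectionError):
            featurize_positions(base, AtomSelection(np.array([], dtype=int)))


class TestSubsample:
    def test_stride_two(self, traj3state):
        _, _, traj, _ = traj3state
        sub = subsample(traj, 2)
        assert sub.n_frames == traj.n_frames // 2 + traj.n_frames % 2
        assert np.array_equal(sub.coordinates[1], traj.coordinates[2])
        assert sub.frame_spacing == traj.frame_spacing * 2

    def test_stride_one_identity(self, traj3state):
        _, _, traj, _ = traj3state
        sub = subsample(traj, 1)
        assert np.array_equal(sub.coordinates, traj.coordinates)

    def test_stride_beyond_length(self, toy10):
        base, _ = toy10
        assert subsample(base, 100).n_frames == 1

    def test_bad_stride(self, toy10):
        base, _ = toy10
        with pytest.raises(InvalidArgumentError):
            subsample(base, 0)
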
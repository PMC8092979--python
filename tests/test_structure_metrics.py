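"""Superposition, per-residue RMSD and side-chain network geometry."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from allopath import (
    CoordinateTrajectory,
    GeneratorConfig,
    build_pscn,
    generate_coordinate_trajectory,
    high_mobility_residues,
    per_residue_rmsd,
    superpose,
)
from allopath.errors import GeometryError
from allopath.structure_metrics import (
    apply_transform,
    read_pdb_trajectory,
    write_pdb_trajectory,
)

RNG = np.random.default_rng(42)


def random_rigid(rng):
    quat = rng.standard_normal(4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    return rot, 10.0 * rng.standard_normal(3)


def brute_force_fit_rmsd(mobile, reference):
    """Best rigid-fit RMSD by direct minimisation over rotation vectors.

    Independent of the Kabsch/quaternion path: centres both point sets
    and polishes a coarse rotation-vector grid with Nelder-Mead.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(rotvec):
        fitted = mob @ Rotation.from_rotvec(rotvec).as_matrix().T
        return float(np.mean(np.sum((fitted - ref) ** 2, axis=1)))

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, 7)
    for x in grid:
        for y in grid:
            for z in grid:
                res = minimize(cost, [x, y, z], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-14})
                best = min(best, res.fun)
    return float(np.sqrt(best))


class TestSuperpose:
    def test_identity_on_equal_frames(self):
        frame = RNG.standard_normal((10, 3))
        rot, trans, rmsd = superpose(frame, frame)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(trans, 0.0, atol=1e-8)
        assert rmsd == pytest.approx(0.0, abs=1e-7)

    def test_rigid_transform_is_removed(self):
        ref = RNG.standard_normal((12, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot90.T + np.array([5.0, 0.0, 0.0])
        rot, trans, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        np.testing.assert_allclose(apply_transform(mobile, rot, trans), ref, atol=1e-8)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_fit_rmsd_matches_brute_force_oracle(self):
        ref = np.array(
            [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 3.0, 0.0], [0.0, 0.0, 3.0]]
        )
        mobile = ref.copy()
        mobile[3] += np.array([0.7, -0.4, 0.6])  # displace one atom ~1 A
        rot, _ = random_rigid(np.random.default_rng(3))
        mobile = mobile @ rot.T + 2.0
        _, _, rmsd = superpose(mobile, ref)
        oracle = brute_force_fit_rmsd(mobile, ref)
        assert rmsd == pytest.approx(oracle, abs=1e-5)

    def test_rmsd_invariant_under_rigid_transform_of_mobile(self):
        ref = RNG.standard_normal((15, 3))
        mobile = ref + 0.3 * RNG.standard_normal((15, 3))
        _, _, base = superpose(mobile, ref)
        for seed in range(5):
            rot, trans = random_rigid(np.random.default_rng(seed))
            _, _, moved = superpose(mobile @ rot.T + trans, ref)
            assert moved == pytest.approx(base, abs=1e-8)

    def test_too_few_atoms_rejected(self):
        pts = RNG.standard_normal((5, 3))
        mask = np.zeros(5, dtype=bool)
        mask[:2] = True
        with pytest.raises(GeometryError):
            superpose(pts, pts, mask)

    def test_collinear_atoms_rejected(self):
        line = np.outer(np.arange(4, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            superpose(line, line)


class TestPerResidueRmsd:
    def test_static_trajectory_is_zero(self):
        config = GeneratorConfig(
            n_residues=20, n_snapshots=10, pathway_residues=(5,), sources=(8,),
            sinks=(12,), coord_frames=6, loop_displacement=0.0,
            thermal_sigma=0.0, rigid_jitter=False, seed=1,
        )
        traj, _ = generate_coordinate_trajectory(config)
        rmsd = per_residue_rmsd(traj)
        assert max(rmsd.values()) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_jitter_only_removed_by_superposition(self):
        config = GeneratorConfig(
            n_residues=20, n_snapshots=10, pathway_residues=(5,), sources=(8,),
            sinks=(12,), coord_frames=6, loop_displacement=0.0,
            thermal_sigma=0.0, rigid_jitter=True, seed=2,
        )
        traj, _ = generate_coordinate_trajectory(config)
        rmsd = per_residue_rmsd(traj)
        assert max(rmsd.values()) < 1e-6

    def test_planted_loop_recovered_scaffold_quiet(self):
        config = GeneratorConfig(seed=9, coord_frames=40)
        traj, truth = generate_coordinate_trajectory(config)
        rmsd = per_residue_rmsd(traj)
        loop = set(truth.loop_residues)
        assert all(rmsd[r] > 10.0 for r in loop)
        assert max(v for r, v in rmsd.items() if r not in loop) < 1.0
        assert high_mobility_residues(rmsd) == sorted(loop)

    def test_window_bounds_validated(self):
        config = GeneratorConfig(
            n_residues=10, n_snapshots=10, pathway_residues=(3,), sources=(5,),
            sinks=(7,), coord_frames=5, seed=0,
        )
        traj, _ = generate_coordinate_trajectory(config)
        with pytest.raises(ValueError):
            per_residue_rmsd(traj, window=5)

    def test_pdb_round_trip(self, tmp_path):
        config = GeneratorConfig(
            n_residues=8, n_snapshots=4, pathway_residues=(3,), sources=(5,),
            sinks=(7,), coord_frames=3, rigid_jitter=False, seed=4,
        )
        traj, _ = generate_coordinate_trajectory(config)
        path = tmp_path / "traj.pdb"
        write_pdb_trajectory(traj, path)
        back = read_pdb_trajectory(path)
        assert back.n_frames == traj.n_frames
        assert back.n_atoms == traj.n_atoms
        # PDB coordinate fields carry 3 decimals
        np.testing.assert_allclose(back.frames, traj.frames, atol=2e-3)
        assert np.array_equal(back.atom_residue_ids, traj.atom_residue_ids)


class TestHighMobilityFilter:
    def test_strict_threshold(self):
        assert high_mobility_residues({54: 11.0, 60: 2.0}) == [54]
        assert high_mobility_residues({54: 10.0}) == []  # ties excluded

    def test_all_below_gives_empty(self):
        assert high_mobility_residues({1: 0.1, 2: 9.99}) == []


class TestPscn:
    @staticmethod
    def ca_only(positions):
        positions = np.asarray(positions, dtype=float)
        n = len(positions)
        return (
            positions,
            np.arange(1, n + 1),
            np.array(["CA"] * n, dtype=object),
        )

    def test_far_pair_has_no_edge(self):
        coords, rids, names = self.ca_only([[0, 0, 0], [25.0, 0, 0]])
        graph = build_pscn(coords, rids, names, cutoff=20.0)
        assert graph.number_of_edges() == 0
        assert set(graph.nodes) == {1, 2}

    def test_close_pair_edge_carries_distance(self):
        coords, rids, names = self.ca_only([[0, 0, 0], [3.0, 0, 0]])
        graph = build_pscn(coords, rids, names, cutoff=20.0)
        assert graph.number_of_edges() == 1
        assert graph.edges[1, 2]["distance"] == pytest.approx(3.0)

    def test_linear_chain_matches_all_pairs_oracle(self):
        # 10 residues on a line at 4 A spacing, cutoff 20 A
        pos = np.outer(np.arange(10, dtype=float) * 4.0, [1.0, 0.0, 0.0])
        coords, rids, names = self.ca_only(pos)
        graph = build_pscn(coords, rids, names, cutoff=20.0)
        expected = {
            (i + 1, j + 1)
            for i in range(10)
            for j in range(i + 1, 10)
            if np.linalg.norm(pos[i] - pos[j]) <= 20.0
        }
        assert {tuple(sorted(e)) for e in graph.edges} == expected

    def test_random_frame_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        pos = 12.0 * rng.standard_normal((25, 3))
        coords, rids, names = self.ca_only(pos)
        for cutoff in (5.0, 10.0, 20.0):
            graph = build_pscn(coords, rids, names, cutoff=cutoff)
            expected = {
                (i + 1, j + 1)
                for i in range(25)
                for j in range(i + 1, 25)
                if np.linalg.norm(pos[i] - pos[j]) <= cutoff
            }
            assert {tuple(sorted(e)) for e in graph.edges} == expected

    def test_side_chain_centroid_used_when_present(self):
        # residue 1: side-chain atom 1 A from residue 2's CA; backbone far
        coords = np.array(
            [[0.0, 0.0, 0.0], [29.0, 0.0, 0.0], [30.0, 0.0, 0.0]]
        )
        rids = np.array([1, 1, 2])
        names = np.array(["CA", "CB", "CA"], dtype=object)
        graph = build_pscn(coords, rids, names, cutoff=20.0)
        # centroid of residue 1 side chain = CB at x=29 -> distance 1 <= 20
        assert graph.has_edge(1, 2)
        assert graph.edges[1, 2]["distance"] == pytest.approx(1.0)
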
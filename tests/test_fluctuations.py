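"""Block-averaged MSF: hand examples, oracles, invariances, OU recovery."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import double_loop_global_msf
from ptfluct.core import Atom, BlockSpec, Box, Topology, Trajectory
from ptfluct.errors import CoverageError, SelectionError, ShapeError
from ptfluct.fluctuations import compute_msf, delta_msf_map
from ptfluct.synth import KB_KCAL_MOL_K, OUProteinSpec, generate_ou_protein


def protein_trajectory(coords, frame_interval=1.0):
    n_atoms = coords.shape[1]
    atoms = [
        Atom(i, f"C{i}", "C", i // 2, "ALA", is_protein=True)
        for i in range(n_atoms)
    ]
    box = Box.cubic(100.0)
    return Trajectory(
        topology=Topology(atoms),
        coordinates=coords,
        boxes=[box] * coords.shape[0],
        frame_interval=frame_interval,
    )


class TestComputeMsf:
    def test_identical_frames_give_zero(self):
        coords = np.tile(np.random.default_rng(0).uniform(0, 50, (1, 6, 3)),
                         (20, 1, 1))
        traj = protein_trajectory(coords)
        res = compute_msf(traj, BlockSpec(10.0, 2), superpose=False)
        assert res.global_msf < 1e-24  # zero up to summation round-off
        assert np.all(res.per_atom_mean < 1e-24)

    def test_two_frame_hand_example(self):
        # one atom at x = 0 then x = 2: mean (1,0,0), deviations ±1 → ⟨Δr²⟩ = 1
        coords = np.zeros((2, 1, 3))
        coords[1, 0, 0] = 2.0
        traj = protein_trajectory(coords)
        res = compute_msf(traj, BlockSpec(2.0, 1), superpose=False)
        assert np.isclose(res.global_msf, 1.0)

    def test_matches_double_loop_oracle(self, ou_trajectory):
        traj, _ = ou_trajectory
        res = compute_msf(traj, BlockSpec(2000.0, 5), superpose=False)
        assert np.isclose(
            res.global_msf,
            double_loop_global_msf(res.per_atom_per_block),
            rtol=1e-10,
        )

    def test_per_residue_mean_averages_member_atoms(self, ou_trajectory):
        traj, _ = ou_trajectory
        res = compute_msf(traj, BlockSpec(2000.0, 5), superpose=False)
        res_of = traj.topology.residue_indices[res.atom_indices]
        for k, r in enumerate(res.residue_indices):
            assert np.isclose(
                res.per_residue_mean[k], res.per_atom_mean[res_of == r].mean()
            )

    def test_ou_recovery_within_5pct(self, ou_trajectory):
        traj, spec = ou_trajectory
        res = compute_msf(traj, BlockSpec(2000.0, 5), superpose=False)
        true = spec.msf_true()
        rel = np.abs(res.per_atom_mean - true) / true
        assert np.mean(rel < 0.05) >= 0.95
        assert abs(res.global_msf - true.mean()) / true.mean() < 0.02

    def test_rigid_body_motion_removed_by_superposition(self, ou_trajectory):
        traj, _ = ou_trajectory
        short = Trajectory(
            topology=traj.topology,
            coordinates=traj.coordinates[:2000].copy(),
            boxes=traj.boxes[:2000],
            frame_interval=traj.frame_interval,
        )
        base = compute_msf(short, BlockSpec(1000.0, 2), superpose=True)
        rng = np.random.default_rng(5)
        moved = short.coordinates.copy()
        for f in range(moved.shape[0]):
            r = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-20, 20, 3)
            moved[f] = moved[f] @ r.T + t
        traj2 = Trajectory(
            topology=short.topology,
            coordinates=moved,
            boxes=short.boxes,
            frame_interval=short.frame_interval,
        )
        res2 = compute_msf(traj2, BlockSpec(1000.0, 2), superpose=True)
        assert abs(res2.global_msf - base.global_msf) / base.global_msf < 1e-6

    def test_atom_relabeling_invariance(self, ou_trajectory):
        traj, _ = ou_trajectory
        rng = np.random.default_rng(9)
        perm = rng.permutation(traj.topology.n_atoms)
        atoms = []
        for new_i, old_i in enumerate(perm):
            a = traj.topology.atoms[old_i]
            atoms.append(
                Atom(new_i, a.name, a.element, a.residue_index, a.residue_name,
                     is_protein=a.is_protein)
            )
        permuted = Trajectory(
            topology=Topology(atoms),
            coordinates=traj.coordinates[:, perm, :].copy(),
            boxes=traj.boxes,
            frame_interval=traj.frame_interval,
        )
        a = compute_msf(traj, BlockSpec(2000.0, 5), superpose=False)
        b = compute_msf(permuted, BlockSpec(2000.0, 5), superpose=False)
        assert np.isclose(a.global_msf, b.global_msf, rtol=1e-12)
        assert np.allclose(np.sort(a.per_atom_mean), np.sort(b.per_atom_mean))

    def test_error_shrinks_with_more_blocks(self):
        # SEM over blocks should scale roughly 1/sqrt(n_blocks) on OU data
        spec = OUProteinSpec(n_residues=5, atoms_per_residue=2, kappa=0.05,
                             friction=0.5, n_frames=16_000, seed=21)
        traj = generate_ou_protein(spec)
        few = compute_msf(traj, BlockSpec(4000.0, 4), superpose=False)
        many = compute_msf(traj, BlockSpec(1000.0, 16), superpose=False)
        assert many.global_error < few.global_error * 1.2

    def test_short_trajectory_is_coverage_error(self):
        traj = protein_trajectory(np.zeros((5, 2, 3)))
        with pytest.raises(CoverageError):
            compute_msf(traj, BlockSpec(100.0, 5))

    def test_no_protein_heavy_atoms_is_selection_error(self):
        atoms = [Atom(0, "O", "O", 0, "HOH", is_water=True)]
        traj = Trajectory(Topology(atoms), np.zeros((10, 1, 3)),
                          [Box.cubic(10.0)] * 10)
        with pytest.raises(SelectionError):
            compute_msf(traj, BlockSpec(10.0, 1))


class TestDeltaMsfMap:
    def _result(self, traj, blocks=None):
        return compute_msf(traj, blocks or BlockSpec(2000.0, 5),
                           superpose=False)

    def test_identical_conditions_give_zero_map(self, ou_trajectory):
        traj, _ = ou_trajectory
        res = self._result(traj)
        dmap = delta_msf_map(res, res)
        assert np.all(dmap.delta == 0.0)

    def test_softened_residue_shows_positive_delta(self):
        # residue 0's spring constant halves (fluctuation doubles)
        base_kappa = np.full(10, 0.05)
        soft_kappa = base_kappa.copy()
        soft_kappa[:2] = 0.025
        common = dict(n_residues=5, atoms_per_residue=2, friction=0.5,
                      n_frames=8000, seed=31)
        a = compute_msf(generate_ou_protein(OUProteinSpec(kappa=base_kappa, **common)),
                        BlockSpec(2000.0, 4), superpose=False)
        b = compute_msf(generate_ou_protein(OUProteinSpec(kappa=soft_kappa, **common)),
                        BlockSpec(2000.0, 4), superpose=False)
        dmap = delta_msf_map(a, b)
        expected_jump = 3 * KB_KCAL_MOL_K * 279.0 * (1 / 0.025 - 1 / 0.05)
        assert dmap.delta[0] > expected_jump * 0.7
        assert np.all(np.abs(dmap.delta[1:]) < expected_jump * 0.3)

    def test_color_coordinate_clips_at_anchors(self, ou_trajectory):
        traj, _ = ou_trajectory
        res = self._result(traj)
        dmap = delta_msf_map(res, res)
        dmap.delta[:] = 3.0  # beyond the 2.0 Å² anchor
        assert np.all(dmap.color_coordinate == 1.0)
        dmap.delta[:] = -1.0  # below the −0.5 Å² anchor
        assert np.all(dmap.color_coordinate == 0.0)
        dmap.delta[:] = 0.0  # the white mid-anchor
        assert np.allclose(dmap.color_coordinate, 0.2)

    def test_residue_mismatch_rejected(self, ou_trajectory):
        traj, _ = ou_trajectory
        res = self._result(traj)
        other = self._result(traj)
        other.residue_indices = other.residue_indices[:-1]
        other.per_residue_mean = other.per_residue_mean[:-1]
        with pytest.raises(ShapeError):
            delta_msf_map(res, other)
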
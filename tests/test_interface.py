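"""Interface residues, interaction typing, motif status and SASA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from idpcircuit.io import AtomRecord, ConformerFrame, PoseSet
from idpcircuit.interface import (
    interface_residues,
    motif_status,
    region_binding_fractions,
    relative_sasa,
    shrake_rupley_sasa,
    type_interactions,
)
from idpcircuit.sequence import RegionMap
from idpcircuit.synth import DimerSpec, InteractionSpec, make_dimer_pose


def _region_map_20():
    rm = RegionMap(chain_length=20)
    rm.add("NR", 1, 10)
    rm.add("CR", 11, 20)
    return rm


class TestInterfaceResidues:
    def test_designed_interface_exact(self):
        spec = DimerSpec(20, 20, [
            InteractionSpec("hydrogen_bond", r, r + 1) for r in (2, 5, 8, 11, 14, 17)
        ])
        pose = make_dimer_pose(spec, seed=0)
        rec, lig = interface_residues(pose)
        assert rec == {2, 5, 8, 11, 14, 17}
        assert lig == {3, 6, 9, 12, 15, 18}

    def test_separated_chains_empty(self):
        pose = make_dimer_pose(DimerSpec(6, 6, []), seed=0)
        rec, lig = interface_residues(pose)
        assert rec == set() and lig == set()

    def test_chain_swap_symmetry(self, four_type_pose):
        rec, lig = interface_residues(four_type_pose, receptor_chain="A", ligand_chain="B")
        lig2, rec2 = interface_residues(four_type_pose, receptor_chain="B", ligand_chain="A")
        assert rec == rec2 and lig == lig2

    def test_single_chain_rejected(self):
        atoms = [AtomRecord("CA", "C", r, "GLY", "A", 4.0 * r, 0, 0) for r in range(1, 5)]
        with pytest.raises(ValueError, match="2 chains"):
            interface_residues(ConformerFrame(atoms))


class TestTypeInteractions:
    def test_each_designed_type_found(self, four_type_pose):
        recs = type_interactions(four_type_pose)
        found = {(r.interaction_type, r.residue_a, r.residue_b) for r in recs}
        assert found == {
            ("salt_bridge", 3, 4),
            ("hydrogen_bond", 6, 7),
            ("pi_cation", 9, 2),
            ("pi_stacking", 11, 10),
        }

    def test_measurements_inside_windows(self, four_type_pose):
        for r in type_interactions(four_type_pose):
            if r.interaction_type == "hydrogen_bond":
                assert r.distance <= 3.5
            elif r.interaction_type == "salt_bridge":
                assert r.distance <= 4.0
            elif r.interaction_type == "pi_cation":
                assert r.distance <= 6.0 and r.angle <= 45.0
            elif r.interaction_type == "pi_stacking":
                assert r.distance <= 5.5 and (r.angle <= 30.0 or r.angle >= 60.0)

    def test_rigid_motion_invariance(self, four_type_pose):
        rot = Rotation.from_rotvec([0.4, 1.2, -0.3])
        moved = four_type_pose.with_coords(rot.apply(four_type_pose.coords) + 7.0)
        a = {(r.interaction_type, r.residue_a, r.residue_b)
             for r in type_interactions(four_type_pose)}
        b = {(r.interaction_type, r.residue_a, r.residue_b)
             for r in type_interactions(moved)}
        assert a == b

    def test_distant_rings_no_record(self):
        pose = make_dimer_pose(DimerSpec(8, 8, []), seed=1)
        assert type_interactions(pose) == []


class TestRegionFractions:
    def _pose_set(self, compositions, n_receptor=20, seed=0):
        poses, names = [], []
        for k, residues in enumerate(compositions):
            ints = [
                InteractionSpec("hydrogen_bond", r, 2 * m + 1)
                for m, r in enumerate(residues)
            ]
            poses.append(make_dimer_pose(
                DimerSpec(n_receptor, 2 * len(residues) + 2, ints), seed=seed + k))
            names.append(f"p{k}.pdb")
        return PoseSet(poses, names)

    def test_all_cr(self):
        ps = self._pose_set([(12, 15), (13, 17), (11, 19)])
        summary = region_binding_fractions(ps, _region_map_20())
        assert (summary.fraction_nr, summary.fraction_dual, summary.fraction_cr) == (0, 0, 1)

    def test_mixed_composition(self):
        """3 NR-only, 2 CR-only, 5 mixed 50/50 -> (0.3, 0.5, 0.2) at dominance 0.8."""
        comp = [(2, 5)] * 3 + [(12, 15)] * 2 + [(2, 15)] * 5
        ps = self._pose_set(comp)
        summary = region_binding_fractions(ps, _region_map_20())
        assert summary.fraction_nr == pytest.approx(0.3)
        assert summary.fraction_cr == pytest.approx(0.2)
        assert summary.fraction_dual == pytest.approx(0.5)
        total = summary.fraction_nr + summary.fraction_cr + summary.fraction_dual
        assert total == pytest.approx(1.0)

    def test_dominance_one_forces_dual(self):
        ps = self._pose_set([(2, 15)])
        summary = region_binding_fractions(ps, _region_map_20(), dominance=1.0)
        assert summary.fraction_dual == 1.0

    def test_empty_pose_set_rejected(self):
        with pytest.raises(ValueError):
            region_binding_fractions(PoseSet([], []), _region_map_20())


class TestMotifStatus:
    def test_blockade_fraction_from_composition(self):
        """Motif [2,5] buried in 4 of 8 poses -> blockade fraction 0.5."""
        poses = []
        for k in range(8):
            if k < 4:
                ints = [InteractionSpec("hydrogen_bond", r, r) for r in (2, 3, 4, 5)]
            else:
                ints = [InteractionSpec("hydrogen_bond", 15, 2)]
            poses.append(make_dimer_pose(DimerSpec(20, 12, ints), seed=k))
        ps = PoseSet(poses, [f"p{k}.pdb" for k in range(8)])
        statuses, frac = motif_status(ps, (2, 5))
        assert frac == pytest.approx(0.5)
        assert statuses[:4] == ["blocked"] * 4

    def test_far_motif_exposed(self):
        poses = [make_dimer_pose(
            DimerSpec(20, 8, [InteractionSpec("hydrogen_bond", 15, 3)]), seed=k)
            for k in range(3)]
        ps = PoseSet(poses, [f"p{k}.pdb" for k in range(3)])
        statuses, frac = motif_status(ps, (2, 5))
        assert statuses == ["exposed"] * 3
        assert frac == 0.0

    def test_single_touching_residue_partial(self):
        pose = make_dimer_pose(
            DimerSpec(20, 8, [InteractionSpec("hydrogen_bond", 5, 3)]), seed=1)
        ps = PoseSet([pose], ["p.pdb"])
        statuses, _ = motif_status(ps, (2, 5))
        assert statuses == ["partially_involved"]

    def test_blockade_monotone_in_blocked_fraction(self):
        pose = make_dimer_pose(
            DimerSpec(20, 10, [InteractionSpec("hydrogen_bond", r, r) for r in (2, 3)]),
            seed=2)
        ps = PoseSet([pose], ["p.pdb"])
        fracs = [motif_status(ps, (2, 5), blocked_fraction=b)[1] for b in (0.25, 0.5, 0.9)]
        assert fracs == sorted(fracs, reverse=True)

    def test_motif_outside_chain(self):
        pose = make_dimer_pose(DimerSpec(10, 8, []), seed=0)
        ps = PoseSet([pose], ["p.pdb"])
        with pytest.raises(IndexError):
            motif_status(ps, (5, 40))


class TestSASA:
    def test_isolated_atom_closed_form(self):
        frame = ConformerFrame([AtomRecord("CA", "C", 1, "GLY", "A", 0, 0, 0)])
        sasa, _ = shrake_rupley_sasa(frame, n_points=4000)
        expect = 4.0 * np.pi * (1.70 + 1.4) ** 2
        assert sasa[("A", 1)] == pytest.approx(expect, rel=1e-6)

    def test_matches_mdtraj_on_small_frame(self, tmp_path, four_type_pose):
        """Independent cross-check against an established implementation."""
        mdtraj = pytest.importorskip("mdtraj")
        from idpcircuit.io import write_pdb
        p = tmp_path / "pose.pdb"
        write_pdb(four_type_pose, p)
        traj = mdtraj.load_pdb(str(p))
        ref = mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960,
                                   mode="residue")[0] * 100.0  # nm² -> Å²
        ours, _ = shrake_rupley_sasa(four_type_pose, n_points=960)
        keys = sorted(ours)
        got = np.array([ours[k] for k in keys])
        # radii tables differ slightly between implementations
        assert np.abs(got - ref).max() / ref.max() < 0.05

    def test_buried_core_low_relative_sasa(self):
        rng = np.random.default_rng(0)
        atoms = [AtomRecord("CA", "C", 1, "ALA", "A", 0, 0, 0)]
        shell = rng.normal(size=(200, 3))
        shell = 3.5 * shell / np.linalg.norm(shell, axis=1, keepdims=True)
        jitter = rng.uniform(0.0, 2.0, size=(200, 1))
        shell = shell * (1.0 + jitter / 3.5)
        for k, p in enumerate(shell):
            atoms.append(AtomRecord("CA", "C", k + 2, "ALA", "A", *p))
        rel = relative_sasa(ConformerFrame(atoms))
        assert rel[("A", 1)] < 0.05

    def test_complexation_never_increases_sasa(self, four_type_pose):
        sasa_complex, _ = shrake_rupley_sasa(four_type_pose, n_points=480)
        for chain in four_type_pose.chain_ids:
            sel = four_type_pose.select(chain_id=chain)
            mono = ConformerFrame([four_type_pose.atoms[k] for k in sel])
            sasa_mono, _ = shrake_rupley_sasa(mono, n_points=480)
            total_complex = sum(v for (c, _), v in sasa_complex.items() if c == chain)
            total_mono = sum(sasa_mono.values())
            assert total_complex <= total_mono + 1e-6

    def test_unknown_element_needs_fallback(self):
        frame = ConformerFrame([AtomRecord("XX", "XX", 1, "UNK", "A", 0, 0, 0)])
        with pytest.raises(KeyError):
            shrake_rupley_sasa(frame)
        sasa, _ = shrake_rupley_sasa(frame, fallback_radius=1.8)
        assert sasa[("A", 1)] == pytest.approx(4 * np.pi * (1.8 + 1.4) ** 2, rel=1e-6)
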
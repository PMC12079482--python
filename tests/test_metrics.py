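"""Superposition, RMSF, helicity and GROMOS clustering."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from idpcircuit.metrics import (
    ClusterSolution,
    DegenerateGeometryError,
    assign_secondary_structure,
    gromos_cluster,
    helicity_profile,
    kabsch_superpose,
    rmsf_profile,
    select_representatives,
)
from idpcircuit.io import Ensemble
from idpcircuit.synth import (
    make_contact_scaffold,
    make_extended_chain,
    make_fluctuation_ensemble,
    make_ideal_helix,
    make_torsion_chain,
    make_two_basin_ensemble,
)


class TestKabsch:
    def test_rigid_motion_recovers_zero_rmsd(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(30, 3)) * 5.0
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7])
        moved = rot.apply(cloud) + np.array([10.0, -3.0, 4.0])
        _, rmsd = kabsch_superpose(moved, cloud)
        assert rmsd <= 1e-6

    def test_single_displaced_atom_matches_direct_optimization(self):
        """RMSD from Kabsch equals a direct numeric minimum over rigid motions."""
        rng = np.random.default_rng(1)
        cloud = rng.normal(size=(40, 3)) * 6.0
        other = cloud.copy()
        other[0] += np.array([2.0, 0.0, 0.0])
        _, rmsd = kabsch_superpose(other, cloud)

        def objective(params):
            rot = Rotation.from_rotvec(params[:3])
            moved = rot.apply(other) + params[3:]
            return np.sqrt(((moved - cloud) ** 2).sum(axis=1).mean()) / 10.0

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000}).fun
            for x0 in (np.zeros(6), np.full(6, 0.1))
        )
        assert rmsd == pytest.approx(best, abs=1e-5)
        # and is bounded by the no-rotation alignment d/sqrt(N)
        assert rmsd <= 2.0 / np.sqrt(40) / 10.0 + 1e-9

    def test_mirror_image_not_matched(self):
        rng = np.random.default_rng(2)
        cloud = rng.normal(size=(20, 3)) * 4.0
        mirrored = cloud * np.array([-1.0, 1.0, 1.0])
        _, rmsd = kabsch_superpose(mirrored, cloud)
        assert rmsd > 0.01

    def test_collinear_selection_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line + 1.0)


class TestRMSF:
    def test_rigid_ensemble_zero(self, small_scaffold):
        ens = make_fluctuation_ensemble(small_scaffold, 0.0, 5, seed=1)
        prof = rmsf_profile(ens)
        assert np.allclose(prof.values_nm, 0.0, atol=1e-12)

    def test_gaussian_closed_form(self):
        """Isotropic Gaussian displacements of scale σ give RMSF = σ√3."""
        base = make_contact_scaffold(100, [], seed=3)
        ens = make_fluctuation_ensemble(base, 0.5, 2000, seed=5)
        prof = rmsf_profile(ens)
        expect = 0.5 * np.sqrt(3) / 10.0  # nm
        assert np.abs(prof.values_nm - expect).max() / expect < 0.05

    def test_per_residue_amplitudes_recovered(self):
        base = make_contact_scaffold(40, [], seed=4)
        sigma = np.linspace(0.2, 1.0, 40)
        ens = make_fluctuation_ensemble(base, sigma, 1500, seed=6)
        prof = rmsf_profile(ens, superpose=False)
        expect = sigma * np.sqrt(3) / 10.0
        assert np.abs(prof.values_nm / expect - 1.0).max() < 0.08

    def test_two_frame_displacement_without_fit(self):
        base = make_contact_scaffold(12, [], seed=5)
        coords2 = base.coords.copy()
        sel = base.select(atom_names={"CA"})
        d = 2.0
        res_atoms = base.residue_atom_indices()
        key = sorted(res_atoms)[4]
        coords2[res_atoms[key]] += np.array([d, 0.0, 0.0])
        ens = Ensemble([base, base.with_coords(coords2)])
        prof = rmsf_profile(ens, superpose=False)
        assert prof.values_nm[4] == pytest.approx(d / 2.0 / 10.0)
        others = np.delete(prof.values_nm, 4)
        assert np.allclose(others, 0.0, atol=1e-12)

    def test_single_frame_rejected(self, small_scaffold):
        with pytest.raises(ValueError):
            rmsf_profile(Ensemble([small_scaffold]))


class TestSecondaryStructure:
    def test_ideal_helix_all_h(self, ideal_helix_12):
        assert assign_secondary_structure(ideal_helix_12).all()

    def test_extended_strand_no_h(self):
        assert assign_secondary_structure(make_extended_chain(12)).sum() == 0

    def test_helix_coil_helix_matches_planted(self):
        frame, planted = make_torsion_chain([(8, "helix"), (10, "coil"), (8, "helix")])
        got = assign_secondary_structure(frame)
        assert (got == planted).all()

    def test_short_helical_run_not_called(self):
        frame, _ = make_torsion_chain([(3, "helix"), (10, "coil")])
        assert assign_secondary_structure(frame).sum() == 0


class TestHelicity:
    def test_all_helix_ensemble(self, ideal_helix_12):
        ens = Ensemble([ideal_helix_12] * 4)
        hel = helicity_profile(ens)
        assert hel.content_percent == pytest.approx(100.0)
        assert len(hel.stable_residues) == 12

    def test_partial_occupancy_counting(self):
        helix_part, _ = make_torsion_chain([(15, "coil"), (10, "helix"), (15, "coil")])
        coil_only, _ = make_torsion_chain([(40, "coil")])
        ens = Ensemble([helix_part] + [coil_only] * 3)
        hel = helicity_profile(ens)
        assert hel.content_percent == pytest.approx(10 / (40 * 4) * 100)
        assert len(hel.stable_residues) == 0  # 0.25 < 0.30 threshold

    def test_replicate_dispersion_is_population_std(self):
        reps = []
        for n_hel in (4, 8, 12):
            frame, _ = make_torsion_chain([(n_hel, "helix"), (40 - n_hel, "coil")])
            reps.append(Ensemble([frame] * 2, replicate_id=f"r{n_hel}"))
        hel = helicity_profile(reps)
        contents = [100 * n / 40 for n in (4, 8, 12)]
        assert hel.per_replicate_percent == pytest.approx(contents)
        assert hel.content_percent == pytest.approx(np.mean(contents))
        assert hel.content_std == pytest.approx(np.std(contents))


class TestClustering:
    def test_identical_frames_one_cluster(self, small_scaffold):
        ens = make_fluctuation_ensemble(small_scaffold, 0.0, 6, seed=1)
        sol = gromos_cluster(ens, cutoff_nm=0.9)
        assert sol.sizes == [6]

    def test_two_basin_memberships_exact(self):
        ens, labels = make_two_basin_ensemble(30, 10, seed=7)
        sol = gromos_cluster(ens, cutoff_nm=0.9)
        got = sorted(sorted(m) for m in sol.memberships)
        assert got == [list(range(10)), list(range(10, 20))]

    def test_infinite_cutoff_single_cluster(self):
        ens, _ = make_two_basin_ensemble(20, 5, seed=8)
        sol = gromos_cluster(ens, cutoff_nm=np.inf)
        assert sol.sizes == [10]

    def test_members_within_cutoff_of_center(self):
        ens, _ = make_two_basin_ensemble(25, 8, seed=9)
        from idpcircuit.metrics import pairwise_rmsd_matrix
        D = pairwise_rmsd_matrix(ens)
        sol = gromos_cluster(ens, cutoff_nm=0.9, rmsd_matrix=D)
        for center, members in zip(sol.centers, sol.memberships):
            assert all(D[center, m] <= 0.9 for m in members)

    def test_deterministic(self):
        ens, _ = make_two_basin_ensemble(20, 6, seed=10)
        a = gromos_cluster(ens, cutoff_nm=0.9)
        b = gromos_cluster(ens, cutoff_nm=0.9)
        assert a.memberships == b.memberships and a.centers == b.centers


class TestRepresentatives:
    @pytest.mark.parametrize("sizes,coverage,expected", [
        ([60, 30, 10], 0.5, 1),
        ([30, 25, 25, 20], 0.5, 2),
        ([60, 30, 10], 1.0, 3),
        ([50, 50], 0.5, 1),
    ])
    def test_coverage_rule(self, sizes, coverage, expected):
        members = []
        start = 0
        for s in sizes:
            members.append(list(range(start, start + s)))
            start += s
        sol = ClusterSolution(
            memberships=members,
            centers=[m[0] for m in members],
            cutoff_nm=0.9,
            n_frames=start,
        )
        assert len(select_representatives(sol, coverage)) == expected

    def test_invalid_coverage(self):
        sol = ClusterSolution([[0]], [0], 0.9, 1)
        with pytest.raises(ValueError):
            select_representatives(sol, 0.0)
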
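"""Correlation scoring, rigid fitting, flip disambiguation, clashes, contacts."""

import numpy as np
import pytest

from cryolig import (
    DensityMap,
    LigandPose,
    SimulationParams,
    build_scene,
    clash_check,
    contact_residues,
    correlation_score,
    find_blobs,
    flip_compare,
    make_toy_ligand,
    make_toy_transporter,
    rigid_fit,
    sd_threshold,
    simulate_map,
)
from cryolig.errors import DomainError
from cryolig.fitting import (
    apply_end_swap,
    rotation_angle,
    rotation_grid_spacing,
    super_fibonacci_rotations,
)
from cryolig.structure import AtomRecord, LigandAtoms, ModelStructure

IDENTITY = LigandPose(np.eye(3), np.zeros(3))


def _pair_ligand(d=3.0):
    return LigandAtoms([
        AtomRecord("L", 1, "", "LIG", "C1", "C", (0.0, 0.0, 0.0)),
        AtomRecord("L", 1, "", "LIG", "C2", "C", (d, 0.0, 0.0)),
    ])


class TestRotationLattice:
    def test_all_matrices_are_proper_rotations(self):
        for R in super_fibonacci_rotations(100):
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_covering_improves_with_more_points(self):
        assert rotation_grid_spacing(576) < rotation_grid_spacing(64)


class TestCorrelationScore:
    def test_self_correlation_is_one(self):
        lig = make_toy_ligand(seed=0)
        params = SimulationParams(resolution=5.0, voxel_size=1.0)
        sim = simulate_map(lig, params)
        cc, n = correlation_score(lig, IDENTITY, sim, params)
        assert cc == pytest.approx(1.0, abs=1e-9)
        assert n > 0

    def test_negated_map_gives_minus_one(self):
        lig = make_toy_ligand(seed=0)
        params = SimulationParams(resolution=5.0, voxel_size=1.0)
        sim = simulate_map(lig, params)
        neg = DensityMap(-sim.values, sim.voxel_size, sim.origin)
        cc, _ = correlation_score(lig, IDENTITY, neg, params)
        assert cc == pytest.approx(-1.0, abs=1e-9)

    def test_invariant_under_affine_rescaling(self):
        lig = make_toy_ligand(seed=1)
        params = SimulationParams(resolution=5.0, voxel_size=1.0)
        sim = simulate_map(lig, params)
        rng = np.random.default_rng(0)
        noisy = DensityMap(
            sim.values + rng.normal(0, 0.02 * sim.values.max(), sim.dims),
            sim.voxel_size, sim.origin,
        )
        cc1, _ = correlation_score(lig, IDENTITY, noisy, params)
        scaled = DensityMap(3.7 * noisy.values + 11.0, sim.voxel_size, sim.origin)
        cc2, _ = correlation_score(lig, IDENTITY, scaled, params)
        assert cc2 == pytest.approx(cc1, abs=1e-9)

    def test_true_pose_beats_translated_pose_across_seeds(self):
        lig = make_toy_ligand(seed=0)
        params = SimulationParams()
        wins = 0
        for seed in range(10):
            model = make_toy_transporter(60.0, seed=seed)
            dmap, truth = build_scene(model, ligand=lig, params=params,
                                      noise_sd=0.10, seed=seed)
            pose = truth.pose()
            off = LigandPose(pose.rotation, pose.translation + np.array([5.0, 0, 0]))
            cc_true, _ = correlation_score(lig, pose, dmap, params)
            cc_off, _ = correlation_score(lig, off, dmap, params)
            wins += cc_true > cc_off
        assert wins == 10


class TestRigidFit:
    def test_self_fit_identity(self, ivacaftor):
        params = SimulationParams(resolution=5.0, voxel_size=1.043)
        sim = simulate_map(ivacaftor, params)
        blob = find_blobs(sim, sd_threshold(sim, 7.0), 26, 10)[0]
        pose = rigid_fit(ivacaftor, sim, blob, params, n_rotations=192)
        assert pose.cc >= 0.99
        assert rotation_angle(pose.rotation) <= rotation_grid_spacing(192)

    def test_refinement_never_reduces_cc(self):
        lig = make_toy_ligand(seed=2)
        params = SimulationParams()
        model = make_toy_transporter(60.0, seed=2)
        dmap, truth = build_scene(model, ligand=lig, params=params, seed=2)
        from cryolig import mask_modeled_density, threshold_for_volume

        thr = threshold_for_volume(dmap, truth.display_volume)
        masked, _ = mask_modeled_density(dmap, model, 3.0)
        blob = find_blobs(masked, thr.level, 26, 10)[0]
        coarse = rigid_fit(lig, dmap, blob, params, n_rotations=96, local_refine=False)
        refined = rigid_fit(lig, dmap, blob, params, n_rotations=96, local_refine=True)
        assert refined.cc >= coarse.cc

    def test_invalid_rotation_count(self, random_map):
        lig = make_toy_ligand(seed=0)
        blob = find_blobs(random_map(seed=1), -10.0, 26, 1)[0]
        with pytest.raises(DomainError):
            rigid_fit(lig, random_map(seed=1), blob, n_rotations=0)

    def test_pose_validation(self):
        with pytest.raises(DomainError):
            LigandPose(np.eye(3) * 2.0, np.zeros(3))


class TestFlipCompare:
    def test_symmetric_two_atom_ligand_flip_is_neutral(self):
        lig = _pair_ligand()
        params = SimulationParams(resolution=5.0, voxel_size=1.0)
        sim = simulate_map(lig, params)
        cc_pose, cc_flip = flip_compare(lig, sim, IDENTITY, params)
        assert cc_pose == pytest.approx(cc_flip, abs=1e-6)

    def test_end_swap_moves_fin_end(self):
        lig = make_toy_ligand(seed=0)  # fins at the z=0 end
        swapped = apply_end_swap(lig, IDENTITY)
        posed = swapped.apply(lig.coords)
        # centroid preserved, shaft tip and fin end exchanged
        assert np.allclose(posed.mean(axis=0), lig.coords.mean(axis=0), atol=1e-9)
        shaft_tip = lig.coords[np.argmax(lig.coords[:, 2])]
        assert np.linalg.norm(posed[np.argmax(lig.coords[:, 2])] - shaft_tip) > 5.0

    def test_rocket_scene_prefers_true_orientation(self):
        lig = make_toy_ligand(seed=3)
        params = SimulationParams()
        model = make_toy_transporter(60.0, seed=3)
        dmap, truth = build_scene(model, ligand=lig, params=params, seed=3)
        cc_pose, cc_flip = flip_compare(lig, dmap, truth.pose(), params)
        assert cc_pose > cc_flip

    def test_decision_rule_reports_both_values(self):
        # the published decision: report both CCs, prefer the larger
        lig = make_toy_ligand(seed=3)
        params = SimulationParams()
        model = make_toy_transporter(60.0, seed=3)
        dmap, truth = build_scene(model, ligand=lig, params=params, seed=3)
        swapped = apply_end_swap(lig, truth.pose())
        cc_a, cc_b = flip_compare(lig, dmap, swapped, params)
        # starting from the wrong end, the flip must win
        assert cc_b > cc_a


class TestClashesAndContacts:
    def _protein(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(-10, 10, size=(50, 3))
        return ModelStructure([
            AtomRecord("A", i + 1, "", "GLY", "CA", "C", tuple(c))
            for i, c in enumerate(coords)
        ])

    def test_distant_ligand_has_no_clashes(self):
        lig = _pair_ligand()
        pose = LigandPose(np.eye(3), np.array([100.0, 0.0, 0.0]))
        rep = clash_check(pose, lig, self._protein(), 2.0)
        assert rep.n_serious == 0

    def test_constructed_single_clash(self):
        protein = ModelStructure([
            AtomRecord("A", 42, "", "PHE", "CZ", "C", (0.0, 0.0, 1.5)),
            AtomRecord("A", 99, "", "GLY", "CA", "C", (30.0, 0.0, 0.0)),
        ])
        lig = _pair_ligand()
        rep = clash_check(IDENTITY, lig, protein, 2.0)
        assert rep.n_serious == 1
        li, key, d = rep.pairs[0]
        assert key == ("A", 42, "", "CZ")
        assert d == pytest.approx(1.5)

    def test_pair_set_matches_brute_force(self):
        protein = self._protein()
        lig = LigandAtoms([
            AtomRecord("L", 1, "", "LIG", f"C{i}", "C", tuple(c))
            for i, c in enumerate(np.random.default_rng(5).uniform(-10, 10, (8, 3)))
        ])
        cutoff = 4.0
        rep = clash_check(IDENTITY, lig, protein, cutoff)
        brute = set()
        for i, lc in enumerate(lig.coords):
            for a in protein.atoms:
                if np.linalg.norm(lc - np.array(a.coord)) < cutoff:
                    brute.add((i, a.key))
        assert {(i, k) for i, k, _ in rep.pairs} == brute

    def test_contacts_empty_when_far(self):
        lig = _pair_ligand()
        pose = LigandPose(np.eye(3), np.array([500.0, 0.0, 0.0]))
        assert contact_residues(pose, lig, self._protein(), 4.5) == []

    def test_single_residue_contact(self):
        protein = ModelStructure([
            AtomRecord("A", 339, "", "PHE", "CZ", "C", (0.0, 0.0, 3.0)),
            AtomRecord("B", 7, "", "GLY", "CA", "C", (50.0, 0.0, 0.0)),
        ])
        out = contact_residues(IDENTITY, _pair_ligand(), protein, 4.5)
        assert len(out) == 1
        assert out[0][:3] == ("A", 339, "PHE")
        assert out[0][3] == pytest.approx(3.0)
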
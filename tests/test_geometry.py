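"""Centers of mass, pocket volumes, and iteratively pruned RMSD."""

import numpy as np
import pytest

from cryolig import (
    DensityMap,
    DomainSelection,
    center_of_mass,
    domain_separation,
    kabsch,
    make_toy_transporter,
    matched_rmsd,
    pocket_volume,
)
from cryolig.errors import DomainError, SelectionError
from cryolig.structure import AtomRecord, ModelStructure
from cryolig.synthetic import NBD1_SELECTION, NBD2_SELECTION


def _model(records):
    return ModelStructure(records)


def _ca_trace(coords, chain="A"):
    return [
        AtomRecord(chain, i + 1, "", "GLY", "CA", "C", tuple(c))
        for i, c in enumerate(coords)
    ]


SEL_A = DomainSelection("A", (("A", 1, 9999),))


class TestCenterOfMass:
    def test_two_equal_atoms(self):
        m = _model(_ca_trace([(0, 0, 0), (2, 0, 0)]))
        assert center_of_mass(m, SEL_A) == pytest.approx((1, 0, 0))

    def test_mass_weighting_carbon_oxygen(self):
        m = _model([
            AtomRecord("A", 1, "", "UNK", "C1", "C", (0.0, 0.0, 0.0)),
            AtomRecord("A", 2, "", "UNK", "O1", "O", (1.0, 0.0, 0.0)),
        ])
        x = center_of_mass(m, SEL_A)[0]
        assert x == pytest.approx(15.999 / (12.011 + 15.999), abs=1e-4)

    def test_geometric_equals_mass_for_identical_elements(self):
        rng = np.random.default_rng(3)
        m = _model(_ca_trace(rng.uniform(-5, 5, (20, 3))))
        assert center_of_mass(m, SEL_A, "mass") == pytest.approx(
            center_of_mass(m, SEL_A, "geometric")
        )

    def test_empty_selection(self):
        m = _model(_ca_trace([(0, 0, 0), (1, 1, 1)]))
        with pytest.raises(SelectionError):
            center_of_mass(m, DomainSelection("Z", (("Z", 1, 5),)))


class TestDomainSeparation:
    def test_constructed_sixty_angstrom_pair(self):
        left = _ca_trace([(-30 + dx, dy, 0) for dx in (-1, 1) for dy in (-1, 1)], "A")
        right = _ca_trace([(30 + dx, dy, 0) for dx in (-1, 1) for dy in (-1, 1)], "B")
        m = _model(left + right)
        sep = domain_separation(m, DomainSelection("A", (("A", 1, 99),)),
                                DomainSelection("B", (("B", 1, 99),)))
        assert sep == pytest.approx(60.0, abs=1e-9)

    def test_invariant_under_global_translation(self):
        m1 = make_toy_transporter(56.0, seed=4)
        shifted = ModelStructure([
            AtomRecord(a.chain, a.res_number, a.icode, a.res_name, a.atom_name,
                       a.element, tuple(np.array(a.coord) + [10.0, -4.0, 7.0]))
            for a in m1.atoms
        ])
        s1 = domain_separation(m1, NBD1_SELECTION, NBD2_SELECTION)
        s2 = domain_separation(shifted, NBD1_SELECTION, NBD2_SELECTION)
        assert s1 == pytest.approx(s2, abs=1e-9)

    @pytest.mark.parametrize("sep", [53.0, 56.0, 60.0])
    def test_generated_separation_recovered(self, sep):
        m = make_toy_transporter(sep, seed=11)
        assert domain_separation(m, NBD1_SELECTION, NBD2_SELECTION) == pytest.approx(
            sep, abs=1.0
        )


class TestPocketVolume:
    def test_constant_map_has_no_pocket(self):
        m = DensityMap(np.full((10, 10, 10), 1.0))
        atoms = _ca_trace([(5.0, 5.0, 5.0), (6.0, 5.0, 5.0)])
        assert pocket_volume(m, atoms, 5.0).voxel_count == 0

    def test_single_low_voxel_counted(self):
        vals = np.full((10, 10, 10), 1.0)
        vals[5, 5, 5] = 0.0
        m = DensityMap(vals)
        atoms = _ca_trace([(5.0, 5.0, 5.0)])
        res = pocket_volume(m, atoms, 2.0)
        assert res.voxel_count == 1
        assert res.volume == pytest.approx(m.voxel_volume)

    @pytest.mark.parametrize("seed,n_atoms", [(0, 1), (1, 3), (2, 5)])
    def test_matches_exhaustive_oracle(self, random_map, seed, n_atoms):
        m = random_map(seed=seed, dims=(32, 32, 32))
        rng = np.random.default_rng(seed + 50)
        coords = rng.uniform(5, 27, size=(n_atoms, 3))
        atoms = _ca_trace(coords)
        res = pocket_volume(m, atoms, 5.0)
        mean = m.values.mean()
        count = 0
        for idx in np.ndindex(m.dims):
            center = np.array(idx, float)
            if m.values[idx] < mean and any(
                np.linalg.norm(center - c) <= 5.0 for c in coords
            ):
                count += 1
        assert res.voxel_count == count


class TestKabsch:
    def test_three_point_hand_solvable(self):
        # B is A rotated 90° about z and translated; optimal rmsd is 0
        A = np.array([(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0)])
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        B = (Rz @ A.T).T + np.array([3.0, 4.0, 5.0])
        R, t = kabsch(A, B)
        assert np.allclose((R @ B.T).T + t, A, atol=1e-9)


class TestMatchedRmsd:
    def _trace_model(self, coords, chain="A"):
        return _model(_ca_trace(coords, chain))

    def test_identical_models(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(-10, 10, (30, 3))
        m = self._trace_model(coords)
        rep = matched_rmsd(m, self._trace_model(coords))
        assert rep.rmsd_all == pytest.approx(0.0, abs=1e-12)
        assert rep.n_retained == rep.n_matched == 30

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-10, 10, (50, 3))
        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = (R @ coords.T).T + np.array([5.0, -3.0, 12.0])
        rep = matched_rmsd(self._trace_model(coords), self._trace_model(moved))
        assert rep.rmsd_all < 1e-6

    def test_outlier_pruning_recovers_clean_subset(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-20, 20, (100, 3))
        displaced_idx = rng.choice(100, size=20, replace=False)
        moved = coords.copy()
        for i in displaced_idx:
            direction = rng.normal(size=3)
            moved[i] += 5.0 * direction / np.linalg.norm(direction)
        rep = matched_rmsd(self._trace_model(coords), self._trace_model(moved),
                           prune_cutoff=2.0)
        assert rep.n_retained == 80
        # direct oracle on the clean subset (identical coordinates -> 0)
        clean = np.setdiff1d(np.arange(100), displaced_idx)
        assert rep.rmsd_retained == pytest.approx(0.0, abs=1e-6)
        assert rep.rmsd_all > 1.0
        assert "80 atom pairs within 2" in rep.summary()

    def test_symmetry_of_arguments(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(-10, 10, (40, 3))
        b = a + rng.normal(0, 0.5, (40, 3))
        r1 = matched_rmsd(self._trace_model(a), self._trace_model(b))
        r2 = matched_rmsd(self._trace_model(b), self._trace_model(a))
        assert r1.rmsd_retained == pytest.approx(r2.rmsd_retained, abs=1e-3)
        assert r1.rmsd_all == pytest.approx(r2.rmsd_all, abs=1e-3)

    def test_single_pass_mode(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(-10, 10, (30, 3))
        b = a + rng.normal(0, 1.5, (30, 3))
        rep = matched_rmsd(self._trace_model(a), self._trace_model(b), max_iter=1)
        assert rep.iterations == 1

    def test_too_few_pairs(self):
        a = self._trace_model([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(DomainError):
            matched_rmsd(a, a)
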
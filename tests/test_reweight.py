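"""Ligand placement and Boltzmann reweighting of snapshot populations."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from popshift.constants import kt
from popshift.energy import EnergyModel
from popshift.ensemble import Topology
from popshift.reweight import (
    ApproachSpec,
    boltzmann_reweight,
    effective_sample_size,
    interface_direction,
    place_ligand,
    reweighted_population_analysis,
    weights_from_energy_diff,
)
from conftest import bead_ensemble


def point_top(charges):
    n = len(charges)
    return Topology(np.asarray(charges, float), np.full(n, 3.4), np.full(n, 0.05), np.full(n, 1.7))


class TestInterfaceDirection:
    def test_planar_construction(self):
        protein = np.array(
            [[0.0, 0, 0], [4.0, 0, 0], [0.0, 4, 0], [4.0, 4, 0], [2.0, 2, -6.0]]
        )
        ligand = np.array([[0.0, 0, 2.0], [4.0, 0, 2.0], [0.0, 4, 2.0], [4.0, 4, 2.0]])
        direction = interface_direction(protein, ligand, contact_cutoff=3.0)
        assert np.allclose(direction, [0.0, 0.0, 1.0], atol=1e-6)

    def test_rotation_equivariance(self, rng):
        protein = rng.normal(0, 3, (8, 3))
        ligand = protein.mean(axis=0) + np.array([6.0, 0, 0]) + rng.normal(0, 1, (5, 3))
        d0 = interface_direction(protein, ligand, contact_cutoff=8.0)
        rot = Rotation.random(rng=rng).as_matrix()
        d1 = interface_direction(protein @ rot.T, ligand @ rot.T, contact_cutoff=8.0)
        assert np.allclose(d1, rot @ d0, atol=1e-8)

    def test_too_few_contacts_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            interface_direction(np.zeros((3, 3)), np.full((3, 3), 50.0), contact_cutoff=5.0)


class TestPlaceLigand:
    def make_spec(self):
        pose = np.array([[1.0, 0, 0], [0.0, 1.0, 0], [0.0, 0, 1.0]])
        return ApproachSpec(np.array([0.0, 0.0, 1.0]), (9.0, 12.0, 15.0, 18.0), pose)

    def test_distance_zero_returns_bound_pose(self):
        spec = self.make_spec()
        assert np.array_equal(place_ligand(spec, 0.0), spec.bound_pose)

    @pytest.mark.parametrize("distance", [9.0, 12.0, 15.0, 18.0])
    def test_every_atom_displaced_by_distance(self, distance):
        spec = self.make_spec()
        moved = place_ligand(spec, distance)
        shifts = np.linalg.norm(moved - spec.bound_pose, axis=1)
        assert np.allclose(shifts, distance)

    def test_direction_must_be_unit(self):
        with pytest.raises(ValueError, match="unit"):
            ApproachSpec(np.array([0.0, 0.0, 2.0]), (9.0,), np.zeros((1, 3)))

    def test_rotated_direction_is_unit(self):
        spec = self.make_spec()
        alt = spec.rotated(30.0, np.array([1.0, 0.0, 0.0]))
        assert np.isclose(np.linalg.norm(alt.direction), 1.0)
        assert np.isclose(np.dot(alt.direction, spec.direction), np.cos(np.deg2rad(30)))


class TestWeights:
    def test_constant_energy_gives_uniform(self):
        w = weights_from_energy_diff(np.full(10, 3.3), 300.0)
        assert np.allclose(w, 0.1)

    def test_ln2_energy_split(self):
        temp = 300.0
        delta = np.array([0.0, kt(temp) * np.log(2.0)])
        w = weights_from_energy_diff(delta, temp)
        assert np.allclose(w, [2.0 / 3.0, 1.0 / 3.0])

    def test_overflow_guard(self):
        w = weights_from_energy_diff(np.array([0.0, 1e6]), 300.0)
        assert np.isclose(w.sum(), 1.0)
        assert w[1] == 0.0

    def test_effective_sample_size(self):
        assert np.isclose(effective_sample_size(np.full(50, 0.02)), 50.0)
        w = np.zeros(50)
        w[0] = 1.0
        assert np.isclose(effective_sample_size(w), 1.0)


class TestBoltzmannReweight:
    def scan_setup(self, rng, distances=(9.0, 12.0, 15.0, 18.0)):
        frames = rng.normal(0.0, 1.0, size=(200, 4, 3))
        ens = bead_ensemble(frames)
        protein_top = point_top(rng.normal(0, 0.3, 4))
        ligand_top = point_top([-1.0])
        bound = np.array([[6.0, 0.0, 0.0]])
        spec = ApproachSpec(np.array([1.0, 0.0, 0.0]), tuple(distances), bound)
        return ens, protein_top, ligand_top, spec

    def test_weights_normalized_each_distance(self, rng):
        ens, ptop, ltop, spec = self.scan_setup(rng)
        results = boltzmann_reweight(ens, ptop, ltop, spec)
        assert len(results) == 4
        for res in results:
            assert np.isclose(res.weights.sum(), 1.0, atol=1e-9)
            assert np.all(res.weights >= 0)
            for w in res.component_weights.values():
                assert np.isclose(w.sum(), 1.0, atol=1e-9)

    def test_reference_distance_is_identity(self, rng):
        # ligand placed at the 1000 A reference: dE = 0 exactly, uniform weights
        ens, ptop, ltop, spec = self.scan_setup(rng, distances=(1000.0,))
        res = boltzmann_reweight(ens, ptop, ltop, spec)[0]
        assert np.allclose(res.weights, 1.0 / ens.n_frames, atol=1e-15)

    def test_component_weights_multiply_to_total(self, rng):
        # E_total = E_polar + E_vdw: the two restricted weight sets multiply
        # (up to normalization) to the full weights
        ens, ptop, ltop, spec = self.scan_setup(rng, distances=(9.0,))
        res = boltzmann_reweight(ens, ptop, ltop, spec)[0]
        prod = res.component_weights["elec"] * res.component_weights["vdw"]
        prod /= prod.sum()
        assert np.allclose(prod, res.weights, atol=1e-9)

    def test_favored_substate_monotone_in_distance(self, two_basin_1d, two_basin_samples):
        # negative charge approaching from +x attracts the positive bead:
        # the basin at +2 A gains population as the ligand closes in
        ens = two_basin_samples
        ptop = point_top([0.5])
        ltop = point_top([-1.0])
        spec = ApproachSpec(
            np.array([1.0, 0.0, 0.0]), (9.0, 12.0, 15.0, 18.0), np.array([[8.0, 0.0, 0.0]])
        )
        results = boltzmann_reweight(ens, ptop, ltop, spec, temperature=300.0)
        x = ens.frames[:, 0, 0]
        pops = [res.weights[x > 0].sum() for res in results]  # 9, 12, 15, 18 A
        assert all(a >= b - 1e-12 for a, b in zip(pops, pops[1:]))
        free_pop = (x > 0).mean()
        assert pops[0] > free_pop  # closest approach favors the near basin most


class TestReweightedAnalysis:
    def test_maps_conserve_mass_and_difference_vanishes_at_infinity(self, rng):
        frames = rng.normal(0.0, 1.0, size=(300, 4, 3))
        ens = bead_ensemble(frames)
        ptop = point_top(rng.normal(0, 0.3, 4))
        ltop = point_top([-1.0])
        spec = ApproachSpec(
            np.array([1.0, 0.0, 0.0]), (9.0, 1000.0), np.array([[6.0, 0.0, 0.0]])
        )
        results = boltzmann_reweight(ens, ptop, ltop, spec)
        proj = rng.normal(0.0, 2.0, size=(300, 2))
        analysis = reweighted_population_analysis(results, proj, resolution=0.6)
        for dist, entry in analysis["distances"].items():
            assert np.isclose(entry["map"].densities.sum(), 1.0, atol=1e-9)
            assert abs(entry["difference"].densities.sum()) < 1e-9
            assert np.isclose(entry["projection_1d"].densities.sum(), 1.0, atol=1e-9)
        far = analysis["distances"][1000.0]
        assert np.allclose(far["difference"].densities, 0.0, atol=1e-12)
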
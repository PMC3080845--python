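"""Generator-level checks: Boltzmann correctness of the Metropolis sampler,
closed-form properties of the OU series, ligand constraints, and the
analytic two-state oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from popshift.constants import kt
from popshift.synthetic import (
    BasinSpec,
    ToySystem,
    analytic_two_state_oracle,
    make_toy_ligand,
    make_toy_system,
    sample_langevin_series,
    sample_metropolis,
)


def batch_se(values: np.ndarray, n_blocks: int = 20) -> float:
    """Standard error of the mean of a correlated series via batch means."""
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


class TestToySystem:
    def test_default_preset_has_three_substates(self):
        system = make_toy_system(5)
        assert len(system.basins) == 3
        assert [b.label for b in system.basins] == ["S1", "S2", "S3"]
        # substates separated along one collective (pincer) coordinate
        c1, c2, c3 = (b.center for b in system.basins)
        sep = np.linalg.norm(c2 - c1)
        assert np.isclose(sep, np.linalg.norm(c3 - c2))
        assert np.isclose(sep, 4.0)

    def test_single_basin_two_beads(self):
        basin = BasinSpec(np.zeros(6), 1.0, label="only")
        system = ToySystem([basin], 300.0, np.zeros((2, 3)))
        assert system.dim == 6
        assert np.allclose(system.reference, 0.0)

    def test_seed_determinism(self):
        a = make_toy_system(5, seed=42)
        b = make_toy_system(5, seed=42)
        for ba, bb in zip(a.basins, b.basins):
            assert np.array_equal(ba.center, bb.center)
            assert np.array_equal(ba.stiffness, bb.stiffness)
        assert np.array_equal(a.topology.charge, b.topology.charge)

    @pytest.mark.parametrize(
        "kwargs", [{"temperature": -1.0}, {"temperature": 0.0}, {"n_beads": 1}]
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_toy_system(**{"n_beads": 5, **kwargs})

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ValueError):
            BasinSpec([0.0], [-1.0])


class TestMetropolis:
    def test_harmonic_variance_matches_closed_form(self):
        k, temp = 0.5, 300.0
        basin = BasinSpec([0.0, 0.0, 0.0], [k, 5.0, 5.0], label="b")
        system = ToySystem([basin], temp, np.zeros((1, 3)))
        ens = sample_metropolis(system, 100_000, step_size=0.8, seed=3)
        x = ens.frames[:, 0, 0]
        expected = kt(temp) / k
        dev_sq = (x - x.mean()) ** 2
        se = batch_se(dev_sq)
        assert abs(dev_sq.mean() - expected) < 3 * se

    def test_two_basin_occupancy_ratio(self):
        delta = 0.35  # kcal/mol
        temp = 300.0
        basins = [
            BasinSpec([-2.5, 0, 0], [0.8, 5.0, 5.0], 0.0, "lo"),
            BasinSpec([2.5, 0, 0], [0.8, 5.0, 5.0], delta, "hi"),
        ]
        system = ToySystem(basins, temp, np.zeros((1, 3)))
        ens = sample_metropolis(system, 100_000, step_size=0.9, seed=5)
        x = ens.frames[:, 0, 0]
        in_hi = (x > 0).astype(float)
        p_hi = in_hi.mean()
        expected = 1.0 / (1.0 + np.exp(delta / kt(temp)))
        assert abs(p_hi - expected) < 4 * batch_se(in_hi)

    def test_flat_potential_accepts_everything(self):
        basin = BasinSpec(np.zeros(3), 0.0, label="flat")
        system = ToySystem([basin], 300.0, np.zeros((1, 3)))
        ens = sample_metropolis(system, 2_000, step_size=1.0, seed=0)
        assert ens.meta["acceptance_rate"] == 1.0

    def test_bit_reproducible(self):
        system = make_toy_system(4)
        a = sample_metropolis(system, 2_000, seed=9)
        b = sample_metropolis(system, 2_000, seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_invalid_sampler_inputs(self):
        system = make_toy_system(3)
        with pytest.raises(ValueError):
            sample_metropolis(system, 0)
        with pytest.raises(ValueError):
            sample_metropolis(system, 10, step_size=-0.1)


class TestLangevinSeries:
    def test_single_component_autocorrelation(self):
        from popshift.kinetics import autocorrelation

        series = sample_langevin_series([1.0], [1.0], dt=0.01, n_steps=200_000, seed=2)
        corr = autocorrelation(series, 4.0)
        t = corr["lag_ns"].to_numpy()
        c = corr["value"].to_numpy()
        expected = np.exp(-t)
        # sampling band for a 2000 ns series of a tau=1 ns process
        assert np.max(np.abs(c[t <= 3.0] - expected[t <= 3.0])) < 0.06

    def test_unit_variance(self):
        series = sample_langevin_series([0.4, 12.9], [0.49, 0.51], 0.01, 400_000, seed=4)
        assert abs(series.values.var() - 1.0) < 0.15

    def test_dt_too_large_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            sample_langevin_series([1.0], [1.0], dt=0.6, n_steps=100)

    @pytest.mark.parametrize(
        "tau,amp", [([1.0], [0.5]), ([1.0, 2.0], [0.3, 0.3]), ([-1.0], [1.0]), ([1.0], [0.0])]
    )
    def test_invalid_components_rejected(self, tau, amp):
        with pytest.raises(ValueError):
            sample_langevin_series(tau, amp, dt=0.01, n_steps=100)

    def test_bit_reproducible(self):
        a = sample_langevin_series([0.5, 3.0], [0.4, 0.6], 0.01, 5_000, seed=8)
        b = sample_langevin_series([0.5, 3.0], [0.4, 0.6], 0.01, 5_000, seed=8)
        assert np.array_equal(a.values, b.values)


class TestToyLigand:
    @pytest.mark.parametrize("n_atoms,net_charge", [(1, 1.0), (3, 0.0), (7, -2.0)])
    def test_net_charge_constraint(self, n_atoms, net_charge):
        top, coords = make_toy_ligand(n_atoms, net_charge, seed=1)
        assert coords.shape == (n_atoms, 3)
        assert abs(top.charge.sum() - net_charge) < 1e-12

    def test_determinism_and_validation(self):
        a = make_toy_ligand(4, 1.0, seed=3)
        b = make_toy_ligand(4, 1.0, seed=3)
        assert np.array_equal(a[0].charge, b[0].charge)
        assert np.array_equal(a[1], b[1])
        with pytest.raises(ValueError):
            make_toy_ligand(0)


class TestTwoStateOracle:
    def symmetric_basins(self):
        return [
            BasinSpec([-2.0, 0, 0], [0.5, 5.0, 5.0], 0.0, "A"),
            BasinSpec([2.0, 0, 0], [0.5, 5.0, 5.0], 0.0, "B"),
        ]

    def test_symmetric_unperturbed(self):
        p = analytic_two_state_oracle(self.symmetric_basins(), 0.0, 300.0)
        assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    def test_ln2_offset_gives_two_thirds(self):
        temp = 300.0
        # stiff basins: cross-midpoint leakage is ~1e-6, Boltzmann ratio = 2
        basins = [
            BasinSpec([-2.0, 0, 0], [3.0, 5.0, 5.0], 0.0, "A"),
            BasinSpec([2.0, 0, 0], [3.0, 5.0, 5.0], kt(temp) * np.log(2.0), "B"),
        ]
        p = analytic_two_state_oracle(basins, 0.0, temp)
        assert np.allclose(p, [2.0 / 3.0, 1.0 / 3.0], atol=1e-5)

    @pytest.mark.parametrize("slope", [-0.4, -0.1, 0.0, 0.2, 0.5])
    def test_quadrature_agreement(self, slope):
        temp = 300.0
        basins = [
            BasinSpec([-1.5, 0, 0], [0.7, 5.0, 5.0], 0.05, "A"),
            BasinSpec([2.0, 0, 0], [0.4, 5.0, 5.0], 0.0, "B"),
        ]
        kbt = kt(temp)

        def density(x):
            total = 0.0
            for b in basins:
                e = 0.5 * b.stiffness[0] * (x - b.center[0]) ** 2 + b.depth_offset
                total += np.exp(-(e + slope * x) / kbt)
            return total

        m = 0.5 * (basins[0].center[0] + basins[1].center[0])
        lo, _ = quad(density, -40, m, limit=200)
        hi, _ = quad(density, m, 40, limit=200)
        expected = np.array([lo, hi]) / (lo + hi)
        p = analytic_two_state_oracle(basins, slope, temp)
        assert np.allclose(p, expected, atol=1e-10)

    def test_rejects_wrong_basin_count(self):
        with pytest.raises(ValueError):
            analytic_two_state_oracle(self.symmetric_basins()[:1], 0.0, 300.0)
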
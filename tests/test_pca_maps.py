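"""PCA model, projections, population/difference maps and substate
detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popshift.pca import (
    PopulationMap,
    difference_map,
    find_substates,
    fit_pca,
    mix_maps,
    mode_amplitudes,
    population_map,
    project,
    read_map,
    substate_average_structure,
    substate_populations,
    write_map,
)


class TestFitPCA:
    def test_identical_frames_zero_eigenvalues(self, rng):
        frame = rng.normal(size=(6, 3))
        model = fit_pca(np.stack([frame] * 4))
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_rank_one_displacement(self, rng):
        base = rng.normal(size=(5, 3))
        direction = rng.normal(size=(5, 3))
        direction /= np.linalg.norm(direction)
        amps = rng.normal(size=12)
        frames = base[None] + amps[:, None, None] * direction[None]
        model = fit_pca(frames)
        assert model.eigenvalue_percent[0] > 100 - 1e-6
        assert np.isclose(model.eigenvalues[0], amps.var(), rtol=1e-9)

    def test_eigenvalue_percent_sums_to_100(self, rng):
        frames = rng.normal(size=(10, 4, 3))
        model = fit_pca(frames)
        assert np.isclose(model.eigenvalue_percent.sum(), 100.0, atol=1e-6)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_components_orthonormal(self, rng):
        model = fit_pca(rng.normal(size=(8, 4, 3)))
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-9)

    def test_too_few_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(1, 4, 3)))


class TestProjection:
    def test_mean_frame_projects_to_zero(self, rng):
        frames = rng.normal(size=(7, 4, 3))
        model = fit_pca(frames)
        assert np.allclose(project(model.mean_frame, model), 0.0, atol=1e-10)

    def test_matches_dot_product_oracle(self, rng):
        frames = rng.normal(size=(6, 5, 3))
        model = fit_pca(frames)
        proj = project(frames, model, n_components=3)
        for i, frame in enumerate(frames):
            dev = (frame - model.mean_frame).ravel()
            for k in range(3):
                assert np.isclose(proj[i, k], dev @ model.components[k], atol=1e-10)

    def test_reference_projection_variance_equals_eigenvalue(self, rng):
        frames = rng.normal(size=(20, 4, 3))
        model = fit_pca(frames)
        proj = project(frames, model, n_components=2)
        assert np.allclose(proj.var(axis=0), model.eigenvalues[:2], atol=1e-9)

    def test_rigid_transform_consistency(self, rng):
        from scipy.spatial.transform import Rotation

        frames = rng.normal(size=(9, 4, 3))
        model = fit_pca(frames)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])
        moved = frames @ rot.T + shift
        model_moved = fit_pca(moved)
        # same transform applied to mean and frames: projections unchanged
        # up to component sign
        p0 = project(frames, model, 2)
        p1 = project(moved, model_moved, 2)
        for k in range(2):
            assert np.allclose(np.abs(p0[:, k]), np.abs(p1[:, k]), atol=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        model = fit_pca(rng.normal(size=(5, 4, 3)))
        with pytest.raises(ValueError):
            project(rng.normal(size=(2, 7, 3)), model)


class TestModeAmplitudes:
    def test_single_residue_mode(self):
        comp = np.zeros(12)
        comp[3:6] = [0.6, 0.8, 0.0]
        comp /= np.linalg.norm(comp)
        from popshift.pca import PCAModel

        model = PCAModel(np.zeros((4, 3)), comp[None], np.array([1.0]))
        amp = mode_amplitudes(model, 0)
        assert np.isclose(amp[1], 1.0)
        assert np.allclose(np.delete(amp, 1), 0.0)

    def test_matches_per_residue_norm(self, rng):
        frames = rng.normal(size=(8, 5, 3))
        model = fit_pca(frames)
        amp = mode_amplitudes(model, 0)
        raw = np.array(
            [np.linalg.norm(model.components[0].reshape(-1, 3)[k]) for k in range(5)]
        )
        assert np.allclose(amp, raw / raw.max(), atol=1e-12)
        assert np.isclose((raw**2).sum(), 1.0, atol=1e-9)


class TestPopulationMap:
    def test_single_point_single_cell(self):
        m = population_map(np.array([[1.0, 2.0]]), 0.4, dim=2)
        assert np.isclose(m.densities.sum(), 1.0)
        assert np.isclose(m.densities.max(), 1.0)

    def test_unsmoothed_equals_counting_oracle(self, rng):
        pts = rng.normal(0.0, 2.0, size=(500, 2))
        res = 0.5
        m = population_map(pts, res, dim=2)
        # brute-force binning
        for _ in range(20):
            p = pts[rng.integers(500)]
            ix = int(np.floor((p[0] - (m.grid_origin[0] - res / 2)) / res))
            iy = int(np.floor((p[1] - (m.grid_origin[1] - res / 2)) / res))
            count = np.sum(
                (np.floor((pts[:, 0] - (m.grid_origin[0] - res / 2)) / res) == ix)
                & (np.floor((pts[:, 1] - (m.grid_origin[1] - res / 2)) / res) == iy)
            )
            assert np.isclose(m.densities[ix, iy], count / 500, atol=1e-12)

    @given(st.integers(0, 2**31 - 1), st.booleans())
    @settings(max_examples=15, deadline=None)
    def test_normalization_property(self, seed, smooth):
        pts = np.random.default_rng(seed).normal(0.0, 2.0, size=(200, 2))
        m = population_map(pts, 0.4, dim=2, smoothing=smooth)
        assert abs(m.densities.sum() - 1.0) < 1e-9
        assert np.all(m.densities >= 0)

    def test_weighted_map(self, rng):
        pts = np.array([[0.0, 0.0], [5.0, 5.0]])
        m = population_map(pts, 0.5, dim=2, weights=np.array([0.25, 0.75]))
        assert np.isclose(m.densities.max(), 0.75)

    def test_1d_map(self, rng):
        m = population_map(rng.normal(size=300), 0.4, dim=1, smoothing=True)
        assert m.dim == 1
        assert abs(m.densities.sum() - 1.0) < 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            population_map(np.empty((0, 2)), 0.4)


class TestDifferenceAndMix:
    def make_pair(self, rng):
        pts_a = rng.normal(0.0, 1.5, size=(400, 2))
        pts_b = rng.normal(0.5, 1.5, size=(400, 2))
        extent = ((-6, 6), (-6, 6))
        a = population_map(pts_a, 0.4, dim=2, extent=extent)
        b = population_map(pts_b, 0.4, dim=2, extent=extent)
        return a, b

    def test_map_minus_itself_is_zero(self, rng):
        a, _ = self.make_pair(rng)
        d = difference_map(a, a)
        assert np.allclose(d.densities, 0.0)

    def test_difference_sums_to_zero_and_matches_subtraction(self, rng):
        a, b = self.make_pair(rng)
        d = difference_map(a, b)
        assert abs(d.densities.sum()) < 1e-9
        assert np.allclose(d.densities, a.densities - b.densities)

    def test_mix_endpoints_and_mass(self, rng):
        a, b = self.make_pair(rng)
        assert np.allclose(mix_maps(a, b, 1.0).densities, a.densities)
        m = mix_maps(a, b, 0.3)
        assert np.allclose(m.densities, 0.3 * a.densities + 0.7 * b.densities)
        assert abs(m.densities.sum() - 1.0) < 1e-9

    def test_grid_mismatch_rejected(self, rng):
        a, _ = self.make_pair(rng)
        other = population_map(rng.normal(size=(50, 2)), 0.3, dim=2)
        with pytest.raises(ValueError, match="grid"):
            difference_map(a, other)


class TestSubstates:
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_k_gaussian_mixture_gives_k_modes(self, k):
        rng = np.random.default_rng(10 + k)
        centers = np.column_stack([8.0 * np.arange(k), np.zeros(k)])
        pts = np.concatenate(
            [rng.normal(c, 0.8, size=(3000, 2)) for c in centers]
        )
        m = population_map(pts, 0.4, dim=2, smoothing=True)
        subs = find_substates(m, min_peak_fraction=0.10)
        assert len(subs) == k
        for s, c in zip(sorted(subs, key=lambda s: s.mode_location[0]), centers):
            assert np.linalg.norm(s.mode_location - c) < 0.5

    def test_labels_ordered_along_pc1(self):
        rng = np.random.default_rng(2)
        pts = np.concatenate(
            [
                rng.normal([-6.0, 0.0], 0.7, size=(4000, 2)),
                rng.normal([6.0, 0.0], 0.7, size=(2000, 2)),
            ]
        )
        subs = find_substates(population_map(pts, 0.4, dim=2, smoothing=True))
        # denser peak first, but labels follow PC1 order
        assert subs[0].peak_density >= subs[1].peak_density
        assert subs[0].label == "S1" and subs[0].mode_location[0] < 0
        assert subs[1].label == "S2"

    def test_signed_map_rejected(self, rng):
        pts = rng.normal(size=(100, 2))
        m = population_map(pts, 0.5, dim=2)
        with pytest.raises(ValueError):
            find_substates(difference_map(m, m))


class TestSubstateAverage:
    def test_identical_frames(self, rng):
        frame = rng.normal(size=(4, 3))
        frames = np.stack([frame] * 5)
        proj = np.zeros((5, 2))
        from popshift.pca import Substate

        sub = Substate("S1", np.zeros(2), 1.0)
        avg, members = substate_average_structure(frames, proj, sub, radius=0.3)
        assert np.allclose(avg, frame)
        assert len(members) == 5

    def test_mean_matches_brute_force(self, rng):
        frames = rng.normal(size=(50, 4, 3))
        proj = rng.normal(0.0, 1.0, size=(50, 2))
        from popshift.pca import Substate

        sub = Substate("S1", np.array([0.2, -0.1]), 1.0)
        avg, members = substate_average_structure(frames, proj, sub, radius=0.7)
        mask = np.linalg.norm(proj - sub.mode_location, axis=1) <= 0.7
        assert np.array_equal(members, np.where(mask)[0])
        assert np.allclose(avg, frames[mask].mean(axis=0))

    def test_no_members_suggests_larger_radius(self, rng):
        from popshift.pca import Substate

        sub = Substate("S1", np.array([100.0, 100.0]), 1.0)
        with pytest.raises(ValueError, match="larger radius"):
            substate_average_structure(
                rng.normal(size=(5, 3, 3)), rng.normal(size=(5, 2)), sub, 0.3
            )


class TestMapIO:
    @pytest.mark.parametrize("dim", [1, 2])
    def test_round_trip(self, rng, tmp_path, dim):
        pts = rng.normal(size=(200, 2))
        m = population_map(pts if dim == 2 else pts[:, 0], 0.4, dim=dim)
        path = tmp_path / "map.tsv"
        write_map(m, path)
        back = read_map(path)
        assert back.same_grid(m)
        assert np.allclose(back.densities, m.densities, atol=1e-12)


def test_substate_population_partition(rng):
    from popshift.pca import Substate

    proj = np.concatenate([rng.normal(-4, 0.5, 60), rng.normal(4, 0.5, 40)])[:, None]
    subs = [Substate("S1", np.array([-4.0]), 1.0), Substate("S2", np.array([4.0]), 1.0)]
    pops = substate_populations(proj, subs)
    assert np.isclose(pops["S1"], 0.6)
    assert np.isclose(pops["S2"], 0.4)
    assert np.isclose(sum(pops.values()), 1.0)
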
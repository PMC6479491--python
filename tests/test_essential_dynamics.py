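import numpy as np
import pytest

import rinflow as rf
from rinflow.essential_dynamics import (KB_KJ_PER_MOL_K, FreeEnergySurface,
                                        ProjectionSeries, cosine_content,
                                        free_energy_surface,
                                        locate_minimum_frames)


class TestFit:
    def test_static_ensemble_zero_spectrum(self, static_ensemble):
        sel = rf.select(static_ensemble.topology, "backbone")
        model = rf.fit_essential_dynamics(static_ensemble, sel)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_single_moving_atom_single_eigenvalue(self):
        """One atom oscillating +-0.1 nm along x: population variance
        0.01 nm^2 must appear as the sole nonzero eigenvalue."""
        ens = rf.generate_ensemble(
            rf.EnsembleSpec(n_residues=6, n_frames=8, fluctuation_profile=0.0,
                            seed=1))
        sel = rf.select(ens.topology, "calpha")
        frames = ens.frames.copy()
        # all other atoms fixed -> superposition is the identity
        target = sel.indices[3]
        frames[::2, target, 0] += 1.0  # 1 A = 0.1 nm
        frames[1::2, target, 0] -= 1.0
        moved = rf.TrajectoryEnsemble(topology=ens.topology, frames=frames,
                                      times=ens.times)
        # fit on the static atoms so the superposition is the identity
        fixed = rf.AtomSelection(
            indices=np.array([i for i in sel.indices if i != target]),
            label="fixed")
        model = rf.fit_essential_dynamics(moved, sel, fit_selection=fixed)
        assert model.eigenvalues[0] == pytest.approx(0.01, rel=1e-10)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-15)
        axis = np.zeros(3 * len(sel))
        axis[9] = 1.0  # x of the 4th selected atom
        assert abs(np.dot(model.eigenvectors[0], axis)) == pytest.approx(1.0, abs=1e-10)

    def test_trace_equals_eigenvalue_sum(self, noisy_ensemble):
        """Oracle: direct covariance computation of the superposed
        coordinates."""
        from rinflow.stability import superpose_ensemble
        sel = rf.select(noisy_ensemble.topology, "backbone")
        model = rf.fit_essential_dynamics(noisy_ensemble, sel)
        frames = superpose_ensemble(noisy_ensemble, sel)
        x = frames[:, sel.indices, :].reshape(noisy_ensemble.n_frames, -1) / 10.0
        cov = np.cov(x.T, ddof=0)
        assert np.trace(cov) == pytest.approx(model.eigenvalues.sum(), rel=1e-8)

    def test_eigenvectors_orthonormal(self, noisy_ensemble):
        sel = rf.select(noisy_ensemble.topology, "backbone")
        model = rf.fit_essential_dynamics(noisy_ensemble, sel)
        gram = model.eigenvectors @ model.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_spectrum_invariant_to_rigid_translation(self, noisy_ensemble):
        sel = rf.select(noisy_ensemble.topology, "backbone")
        base = rf.fit_essential_dynamics(noisy_ensemble, sel)
        shifted = rf.TrajectoryEnsemble(
            topology=noisy_ensemble.topology,
            frames=noisy_ensemble.frames + np.array([10.0, -4.0, 2.0]),
            times=noisy_ensemble.times)
        other = rf.fit_essential_dynamics(shifted, sel)
        np.testing.assert_allclose(other.eigenvalues, base.eigenvalues,
                                   atol=1e-10)

    def test_cumulative_variance_monotone_to_one(self, noisy_ensemble):
        sel = rf.select(noisy_ensemble.topology, "backbone")
        model = rf.fit_essential_dynamics(noisy_ensemble, sel)
        cv = model.cumulative_variance()
        assert np.all(np.diff(cv) >= -1e-12)
        assert cv[-1] == pytest.approx(1.0, rel=1e-10)

    def test_too_few_frames(self, static_ensemble):
        one = rf.TrajectoryEnsemble(topology=static_ensemble.topology,
                                    frames=static_ensemble.frames[:1],
                                    times=static_ensemble.times[:1])
        with pytest.raises(ValueError, match="2 frames"):
            rf.fit_essential_dynamics(one, rf.select(one.topology, "backbone"))


class TestProjection:
    def test_variance_equals_eigenvalue(self, noisy_ensemble):
        sel = rf.select(noisy_ensemble.topology, "backbone")
        model = rf.fit_essential_dynamics(noisy_ensemble, sel)
        proj = rf.project(noisy_ensemble, model, k=5)
        for i in range(5):
            assert np.var(proj.coordinates[:, i]) == pytest.approx(
                model.eigenvalues[i], rel=1e-8, abs=1e-15)

    def test_column_means_zero(self, noisy_ensemble):
        sel = rf.select(noisy_ensemble.topology, "backbone")
        model = rf.fit_essential_dynamics(noisy_ensemble, sel)
        proj = rf.project(noisy_ensemble, model, k=4)
        np.testing.assert_allclose(proj.coordinates.mean(axis=0), 0.0,
                                   atol=1e-10)

    def test_full_rank_reconstruction(self, noisy_ensemble):
        """Back-projection over all modes reproduces the superposed,
        mean-removed coordinates."""
        from rinflow.stability import superpose_ensemble
        sel = rf.select(noisy_ensemble.topology, "backbone")
        model = rf.fit_essential_dynamics(noisy_ensemble, sel)
        k = len(model.eigenvalues)
        proj = rf.project(noisy_ensemble, model, k=k)
        recon = proj.coordinates @ model.eigenvectors
        frames = superpose_ensemble(noisy_ensemble, sel)
        x = frames[:, sel.indices, :].reshape(noisy_ensemble.n_frames, -1) / 10.0
        np.testing.assert_allclose(recon, x - x.mean(axis=0), atol=1e-6)

    def test_k_validation(self, noisy_ensemble):
        sel = rf.select(noisy_ensemble.topology, "backbone")
        model = rf.fit_essential_dynamics(noisy_ensemble, sel)
        with pytest.raises(ValueError):
            rf.project(noisy_ensemble, model, k=0)


class TestCosineContent:
    def _series(self, p, n=1000):
        t = np.linspace(0.0, 100.0, n)
        return ProjectionSeries(times=t, coordinates=np.column_stack([p(t)]))

    def test_half_cosine_is_one(self):
        s = self._series(lambda t: np.cos(np.pi * t / 100.0))
        assert cosine_content(s, 1) == pytest.approx(1.0, abs=0.01)

    def test_full_cosine_is_zero(self):
        s = self._series(lambda t: np.cos(2 * np.pi * t / 100.0))
        assert cosine_content(s, 1) == pytest.approx(0.0, abs=0.01)

    def test_white_noise_small(self):
        """Random (uncorrelated) projections have low cosine content."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            s = self._series(lambda t: rng.normal(size=len(t)))
            assert cosine_content(s, 1) < 0.2

    def test_all_zero_projection_defined_as_zero(self):
        s = self._series(lambda t: np.zeros_like(t))
        with pytest.warns(UserWarning, match="all-zero"):
            assert cosine_content(s, 1) == 0.0

    def test_designed_gaussian_mode_admissible(self):
        mode = rf.CollectiveMode(direction=np.array([1.0, 0, 0]), amplitude=3.0)
        ens = rf.generate_ensemble(
            rf.EnsembleSpec(n_residues=5, n_frames=200,
                            fluctuation_profile=0.05, collective_mode=mode,
                            seed=8))
        sel = rf.select(ens.topology, "backbone")
        model = rf.fit_essential_dynamics(ens, sel)
        proj = rf.project(ens, model, 2)
        assert cosine_content(proj, 1) <= 0.2


class TestFreeEnergySurface:
    def _two_cluster_series(self, n_major=80, n_minor=20):
        x = np.concatenate([np.zeros(n_major), np.ones(n_minor) * 5.0])
        y = np.zeros(n_major + n_minor)
        t = np.arange(n_major + n_minor, dtype=float)
        return ProjectionSeries(times=t, coordinates=np.column_stack([x, y]))

    def test_two_bin_boltzmann_inversion(self):
        """80/20 split at 300 K: minor-bin dG = kB * 300 * ln 4."""
        s = self._two_cluster_series()
        surf = free_energy_surface(s, (1, 2), n_bins=4, temperature=300.0,
                                   force=True)
        populated = surf.counts[surf.counts > 0]
        assert sorted(populated.tolist()) == [20, 80]
        expected = KB_KJ_PER_MOL_K * 300.0 * np.log(4.0)
        finite = surf.delta_g[np.isfinite(surf.delta_g)]
        assert sorted(finite.tolist())[0] == pytest.approx(0.0, abs=1e-12)
        assert sorted(finite.tolist())[-1] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(3.457, abs=0.001)

    def test_counts_conserved_and_masking(self):
        s = self._two_cluster_series()
        surf = free_energy_surface(s, (1, 2), n_bins=8, temperature=300.0,
                                   force=True)
        assert surf.counts.sum() == s.n_frames
        assert np.isnan(surf.delta_g[surf.counts == 0]).all()
        assert np.nanmin(surf.delta_g) == 0.0

    def test_single_bin_degenerate(self):
        t = np.arange(10.0)
        s = ProjectionSeries(times=t, coordinates=np.zeros((10, 2)))
        surf = free_energy_surface(s, (1, 2), n_bins=4, force=True)
        assert surf.counts.sum() == 10
        frames = locate_minimum_frames(surf, s)
        np.testing.assert_array_equal(frames, np.arange(10))

    def test_minimum_frames_from_major_cluster(self):
        s = self._two_cluster_series()
        surf = free_energy_surface(s, (1, 2), n_bins=4, force=True)
        frames = locate_minimum_frames(surf, s)
        np.testing.assert_array_equal(frames, np.arange(80))

    def test_minimum_frames_inside_reported_bin(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(200, 2))
        s = ProjectionSeries(times=np.arange(200.0), coordinates=coords)
        surf = free_energy_surface(s, (1, 2), n_bins=6, force=True)
        frames = locate_minimum_frames(surf, s)
        bx, by = np.unravel_index(np.argmax(surf.counts), surf.counts.shape)
        for f in frames:
            assert surf.edges_x[bx] <= coords[f, 0] <= surf.edges_x[bx + 1]
            assert surf.edges_y[by] <= coords[f, 1] <= surf.edges_y[by + 1]

    def test_admissibility_rule_blocks_cosine_modes(self):
        t = np.linspace(0, 100, 500)
        coords = np.column_stack([np.cos(np.pi * t / 100), np.ones_like(t)])
        s = ProjectionSeries(times=t, coordinates=coords)
        with pytest.raises(ValueError, match="cosine content"):
            free_energy_surface(s, (1, 2), n_bins=8)

    def test_transpose_symmetry(self):
        s = self._two_cluster_series()
        a = free_energy_surface(s, (1, 2), n_bins=4, force=True)
        b = free_energy_surface(s, (2, 1), n_bins=4, force=True)
        np.testing.assert_allclose(a.counts, b.counts.T)

    def test_bin_floor(self):
        s = self._two_cluster_series()
        with pytest.raises(ValueError, match="n_bins"):
            free_energy_surface(s, (1, 2), n_bins=3, force=True)
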
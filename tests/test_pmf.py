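"""WHAM estimation, bootstrap errors, and binding-energy extraction."""

import dataclasses

import numpy as np
import pytest

from junctionmech import pmf
from junctionmech import synthetic as syn

from _oracles import reference_wham


def flat_spec(domain=(0.5, 1.5)):
    return syn.PmfSpec(
        energy=lambda x: np.zeros_like(np.asarray(x, float)),
        domain=domain, temperature_k=310.15,
    )


def aligned_rmsd(estimate, truth):
    """RMSD after removing the free-energy gauge (least-squares shift)."""
    delta = estimate - truth
    delta = delta - delta.mean()
    return float(np.sqrt(np.mean(delta**2)))


class TestBiasPotential:
    def test_values_and_symmetry(self):
        assert pmf.bias_potential(800.0, 1.0, 1.0) == 0.0
        assert pmf.bias_potential(800.0, 1.0, 1.05) == pytest.approx(1.0)
        assert pmf.bias_potential(800.0, 1.0, 0.9) == pytest.approx(
            pmf.bias_potential(800.0, 1.0, 1.1))

    def test_invalid_force_constant(self):
        with pytest.raises(ValueError):
            pmf.bias_potential(-1.0, 1.0, 1.0)


class TestWham:
    def test_flat_landscape_recovered_flat(self):
        # every bin of the anchored profile within 0.2 kJ/mol of constant,
        # binned over the window-covered range so counts dominate shot noise
        windows = syn.gen_umbrella_samples(
            flat_spec(), [0.9, 0.95, 1.0, 1.05, 1.1], 800.0, 5000, seed=1)
        edges = np.linspace(0.85, 1.15, 11)
        profile = pmf.wham(windows, bin_edges_nm=edges, temperature_k=310.15)
        sampled = profile.free_energy_kj_mol[np.isfinite(profile.free_energy_kj_mol)]
        assert profile.converged
        assert np.max(np.abs(sampled - sampled.mean())) < 0.2

    def test_single_window_harmonic_truth(self):
        # truth harmonic at the bias center: the unbiased profile over the
        # sampled range must reproduce the analytic U
        k_truth = 400.0
        spec = syn.PmfSpec(
            energy=lambda x: 0.5 * k_truth * (np.asarray(x, float) - 1.0) ** 2,
            domain=(0.5, 1.5))
        windows = syn.gen_umbrella_samples(spec, [1.0], 800.0, 20_000, seed=2)
        profile = pmf.wham(windows, n_bins=40, temperature_k=310.15)
        sampled = np.isfinite(profile.free_energy_kj_mol)
        truth = spec.energy(profile.grid_nm[sampled])
        assert aligned_rmsd(profile.free_energy_kj_mol[sampled], truth) < 0.3

    def test_double_well_recovery(self):
        spec = syn.double_well_pmf(depth_kj_mol=10.0)
        centers = np.round(np.arange(1.0, 2.0001, 0.05), 3)
        windows = syn.gen_umbrella_samples(spec, centers, 800.0, 5000, seed=3)
        profile = pmf.wham(windows, n_bins=100, temperature_k=spec.temperature_k)
        sampled = np.isfinite(profile.free_energy_kj_mol)
        truth = spec.energy(profile.grid_nm[sampled])
        assert aligned_rmsd(profile.free_energy_kj_mol[sampled], truth) <= 0.3

    def test_window_order_invariance(self):
        windows = syn.gen_umbrella_samples(
            flat_spec(), [0.9, 1.0, 1.1], 800.0, 2000, seed=4)
        edges = np.linspace(0.7, 1.3, 61)
        forward = pmf.wham(windows, bin_edges_nm=edges)
        reordered = pmf.wham(windows[::-1], bin_edges_nm=edges)
        np.testing.assert_allclose(
            forward.free_energy_kj_mol, reordered.free_energy_kj_mol,
            atol=1e-5, equal_nan=True)

    def test_non_overlapping_windows_raise_coverage_error(self):
        rng = np.random.default_rng(5)
        near = pmf.UmbrellaWindow(0.5, 800.0, 0.5 + 0.01 * rng.standard_normal(500))
        far = pmf.UmbrellaWindow(2.5, 800.0, 2.5 + 0.01 * rng.standard_normal(500))
        with pytest.raises(pmf.CoverageError, match="share no histogram bin"):
            pmf.wham([near, far], n_bins=100)

    def test_agrees_with_convex_optimisation_oracle(self):
        spec = syn.double_well_pmf(depth_kj_mol=8.0)
        centers = np.round(np.arange(1.0, 2.0001, 0.05), 3)
        windows = syn.gen_umbrella_samples(spec, centers, 800.0, 3000, seed=6)
        edges = np.linspace(0.95, 2.05, 101)
        ours = pmf.wham(windows, bin_edges_nm=edges, temperature_k=spec.temperature_k,
                        tolerance_kj_mol=1e-8)
        hists = np.stack([np.histogram(w.samples_nm, bins=edges)[0]
                          for w in windows]).astype(float)
        _, oracle_free, h_tot = reference_wham(
            hists, edges, centers, 800.0, spec.temperature_k)
        both = np.isfinite(ours.free_energy_kj_mol) & np.isfinite(oracle_free)
        diff = ours.free_energy_kj_mol[both] - oracle_free[both]
        diff -= diff.mean()  # gauge
        assert np.max(np.abs(diff)) < 0.1


class TestBootstrap:
    def test_deterministic_per_seed(self):
        windows = syn.gen_umbrella_samples(
            flat_spec(), [0.95, 1.0, 1.05], 800.0, 1000, seed=7)
        a = pmf.bootstrap_error(windows, n_boot=20, seed=3, n_bins=40)
        b = pmf.bootstrap_error(windows, n_boot=20, seed=3, n_bins=40)
        np.testing.assert_array_equal(a.per_bin_sd_kj_mol, b.per_bin_sd_kj_mol)
        np.testing.assert_equal(a.delta_g_sd_kj_mol, b.delta_g_sd_kj_mol)

    def test_idealized_histograms_give_zero_error(self):
        # windows whose histograms are exactly the expected biased densities:
        # any window reweighting leaves the WHAM solution unchanged
        edges = np.linspace(0.8, 1.2, 81)
        grid = 0.5 * (edges[:-1] + edges[1:])
        kt = pmf.KB_KJ_MOL_K * 310.15
        centers = np.array([0.95, 1.0, 1.05])
        hists = []
        for c in centers:
            density = np.exp(-0.5 * 800.0 * (grid - c) ** 2 / kt)
            hists.append(1e4 * density / density.sum())
        hists = np.stack(hists)

        rng = np.random.default_rng(0)
        profiles = []
        for _ in range(20):
            weights = rng.dirichlet(np.ones(3)) * 3
            profile = pmf.wham_from_histograms(
                hists, edges, centers, 800.0, temperature_k=310.15,
                window_weights=weights, min_counts=1.0)
            profiles.append(profile.free_energy_kj_mol)
        spread = np.nanstd(np.stack(profiles), axis=0)
        assert np.nanmax(spread) < 1e-4

    def test_error_shrinks_with_sample_size(self):
        centers = [0.9, 0.95, 1.0, 1.05, 1.1]
        small = syn.gen_umbrella_samples(flat_spec(), centers, 800.0, 2000, seed=8)
        large = syn.gen_umbrella_samples(flat_spec(), centers, 800.0, 8000, seed=9)
        err_small = pmf.bootstrap_error(small, n_boot=60, seed=1, n_bins=40,
                                        granularity="samples")
        err_large = pmf.bootstrap_error(large, n_boot=60, seed=1, n_bins=40,
                                        granularity="samples")
        med_small = np.nanmedian(err_small.per_bin_sd_kj_mol)
        med_large = np.nanmedian(err_large.per_bin_sd_kj_mol)
        # 4x samples -> error halves, within 25 % Monte-Carlo slack
        assert med_large == pytest.approx(0.5 * med_small, rel=0.25)


class TestBindingEnergy:
    def _profile(self, grid, free_energy, error=None):
        return pmf.PmfProfile(
            grid_nm=np.asarray(grid, float),
            free_energy_kj_mol=np.asarray(free_energy, float),
            error_kj_mol=None if error is None else np.asarray(error, float),
            reference="min", converged=True, n_iterations=1)

    def test_reported_well_shape_recovered_exactly(self):
        # plateau at 0 with a single -59.4 kJ/mol minimum at xi = 0.9 nm
        grid = np.linspace(0.7, 2.5, 181)
        free = -59.4 * np.exp(-0.5 * ((grid - 0.9) / 0.05) ** 2)
        result = pmf.binding_energy(self._profile(grid, free))
        assert result.delta_g_kj_mol == pytest.approx(-59.4, abs=1e-9)
        assert result.xi_min_nm == pytest.approx(0.9, abs=0.005)
        assert not result.minimum_at_edge

    def test_flat_profile_zero_depth(self):
        grid = np.linspace(0.0, 1.0, 50)
        result = pmf.binding_energy(self._profile(grid, np.zeros(50)))
        assert result.delta_g_kj_mol == 0.0

    def test_gauge_invariance(self):
        grid = np.linspace(0.0, 2.0, 100)
        free = -10.0 * np.exp(-0.5 * ((grid - 0.5) / 0.1) ** 2)
        base = pmf.binding_energy(self._profile(grid, free))
        shifted = pmf.binding_energy(self._profile(grid, free + 123.4))
        assert shifted.delta_g_kj_mol == pytest.approx(base.delta_g_kj_mol)

    def test_minimum_at_edge_warns(self):
        grid = np.linspace(0.0, 1.0, 50)
        free = np.linspace(-5.0, 0.0, 50)  # minimum at first bin
        with pytest.warns(RuntimeWarning, match="edge"):
            result = pmf.binding_energy(self._profile(grid, free))
        assert result.minimum_at_edge

    def test_error_propagated_from_bootstrap_bins(self):
        grid = np.linspace(0.0, 1.0, 50)
        free = -10.0 * np.exp(-0.5 * ((grid - 0.3) / 0.05) ** 2)
        err = np.full(50, 0.5)
        result = pmf.binding_energy(self._profile(grid, free, error=err))
        assert result.error_kj_mol is not None and result.error_kj_mol > 0.5


class TestDepthRecoveryInvariant:
    @pytest.mark.parametrize("depth", [5.0, 20.0])
    def test_toy_depth_recovered(self, depth):
        spec = syn.reference_binding_pmf(depth_kj_mol=depth)
        lo, hi = spec.domain
        centers = np.arange(lo + 0.05, hi - 0.049, 0.05)
        windows = syn.gen_umbrella_samples(spec, centers, 800.0, 5000, seed=10)
        profile = pmf.wham(windows, n_bins=150, temperature_k=spec.temperature_k)
        boot = pmf.bootstrap_error(windows, n_boot=50, seed=11, n_bins=150,
                                   temperature_k=spec.temperature_k)
        estimate = pmf.binding_energy(profile)
        # truth under the estimator's own plateau definition
        sampled = np.isfinite(profile.free_energy_kj_mol)
        truth_curve = spec.energy(profile.grid_nm)
        n_tail = max(1, int(np.ceil(0.1 * truth_curve.size)))
        truth_depth = float(truth_curve[sampled].min()
                            - np.mean(truth_curve[-n_tail:][sampled[-n_tail:]]))
        tolerance = max(0.5, 2.0 * boot.delta_g_sd_kj_mol)
        assert estimate.delta_g_kj_mol == pytest.approx(truth_depth, abs=tolerance)
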
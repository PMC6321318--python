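"""Free and consensus polarizability fitting, charge fitting, M-site scan."""

import numpy as np
import pytest

from coswater.constants import F_ELEC
from coswater.forcefield import RigidWaterGeometry, default_forcefield
from coswater.polfit import (
    InducedPotentialSample,
    consensus_fit,
    fit_induced_dipoles_free,
    fit_static_charges,
    fit_stats,
    induced_potential,
    isotropic,
    partition_subsets,
    run_consensus_pipeline,
    samples_from_dataset,
    scan_msite,
)
from coswater.synthetic import connolly_grid

from kkt_oracle import kkt_consensus_alpha


class TestInducedPotential:
    def test_identical_inputs_zero(self):
        phi = np.array([1.0, 2.0, -3.0])
        assert np.array_equal(induced_potential(phi, phi), np.zeros(3))

    def test_constant_offset_invariance(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert np.allclose(induced_potential(a + 7.5, b + 7.5), induced_potential(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            induced_potential(np.zeros(4), np.zeros(5))


class TestFreeFit:
    def test_forward_model_recovery(self, noiseless_dataset):
        samples = samples_from_dataset(noiseless_dataset)
        truth = noiseless_dataset.solute.alpha_diag
        for s in samples[:5]:
            res = fit_induced_dipoles_free(s)
            assert np.all(np.abs(res.alpha[0] / truth - 1) < 1e-10)
            mu_expected = truth * s.e_field[0] / F_ELEC
            assert np.all(np.abs(res.mu[0] - mu_expected) < 1e-14)

    def test_zero_potential_gives_zero_dipole(self, noiseless_dataset):
        s0 = samples_from_dataset(noiseless_dataset)[0]
        s = InducedPotentialSample(
            0, s0.grid_points, np.zeros(len(s0.grid_points)), s0.e_field, s0.centers
        )
        res = fit_induced_dipoles_free(s)
        assert np.allclose(res.mu, 0.0) and res.chi2 == 0.0

    def test_low_field_dimension_flagged(self, noiseless_dataset):
        s0 = samples_from_dataset(noiseless_dataset)[0]
        e = s0.e_field.copy()
        e[0, 1] = 0.5  # below the 1 kJ/mol/nm/e guard
        s = InducedPotentialSample(0, s0.grid_points, s0.phi_induced, e, s0.centers)
        res = fit_induced_dipoles_free(s)
        assert res.low_field_flags[0, 1]
        assert np.isnan(res.alpha[0, 1])
        assert not res.low_field_flags[0, 0]


class TestPartition:
    def test_500_frames_into_25_disjoint_subsets(self):
        subsets = partition_subsets(range(500), subset_size=20, seed=3)
        assert len(subsets) == 25
        flat = [f for sub in subsets for f in sub]
        assert len(flat) == 500 and len(set(flat)) == 500

    def test_remainder_dropped(self):
        subsets = partition_subsets(range(21), subset_size=20, seed=0)
        assert len(subsets) == 1 and len(subsets[0]) == 20

    def test_reproducible(self):
        assert partition_subsets(range(100), 20, seed=9) == partition_subsets(range(100), 20, seed=9)

    def test_bad_subset_size(self):
        with pytest.raises(ValueError):
            partition_subsets(range(10), subset_size=0)


class TestConsensusFit:
    def test_singleton_subset_equals_free_fit(self, noiseless_dataset):
        s = samples_from_dataset(noiseless_dataset)[0]
        free = fit_induced_dipoles_free(s)
        cons = consensus_fit([s])
        assert np.allclose(cons.alpha, free.alpha[0], rtol=1e-10)

    def test_noiseless_exact_recovery(self, noiseless_dataset):
        samples = samples_from_dataset(noiseless_dataset)
        truth = noiseless_dataset.solute.alpha_diag  # (1.2, 0.9, 1.0)e-3
        cons = consensus_fit(samples[:20])
        assert np.all(np.abs(cons.alpha / truth - 1) < 1e-10)

    def test_matches_explicit_kkt_solve(self, noisy_dataset):
        samples = samples_from_dataset(noisy_dataset)[:20]
        cons = consensus_fit(samples)
        phi_list = [s.phi_induced for s in samples]
        e = np.vstack([s.e_field[0] for s in samples])
        alpha_kkt, _ = kkt_consensus_alpha(
            samples[0].grid_points, samples[0].centers[0], phi_list, e
        )
        assert np.all(np.abs(cons.alpha - alpha_kkt) < 1e-8)

    def test_chi2_consensus_at_least_free(self, noisy_dataset):
        samples = samples_from_dataset(noisy_dataset)[:20]
        cons = consensus_fit(samples)
        free_total = sum(fit_induced_dipoles_free(s).chi2 for s in samples)
        assert cons.chi2 >= free_total - 1e-9 * abs(free_total)

    def test_frame_order_invariance(self, noisy_dataset):
        samples = samples_from_dataset(noisy_dataset)[:10]
        a = consensus_fit(samples)
        b = consensus_fit(samples[::-1])
        assert np.allclose(a.alpha, b.alpha, rtol=1e-10)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-10)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            consensus_fit([])


class TestIsotropic:
    @pytest.mark.parametrize(
        "alpha, expected",
        [
            ((1e-3, 1e-3, 1e-3), 1e-3),
            ((1.19e-3, 0.98e-3, 0.98e-3), 1.05e-3),
        ],
    )
    def test_trace_mean(self, alpha, expected):
        assert isotropic(alpha) == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariant(self):
        assert isotropic((1e-3, 2e-3, 3e-3)) == isotropic((3e-3, 1e-3, 2e-3))

    def test_nan_propagates(self):
        assert np.isnan(isotropic((1e-3, np.nan, 1e-3)))


class TestFitStats:
    def test_hand_computed_summary(self):
        # 9-element set; oracle: manual type-7 quantiles (sorted ranks,
        # h = (n-1) p, linear interpolation): q1 = 3.0, med = 5.0, q3 = 7.0
        from coswater.polfit import _summarize

        data = np.array([9.0, 1.0, 5.0, 3.0, 7.0, 2.0, 8.0, 4.0, 6.0])
        s = _summarize(data)
        assert s.q1 == 3.0 and s.median == 5.0 and s.q3 == 7.0
        assert s.whisker_low == 1.0 and s.whisker_high == 9.0
        assert len(s.outliers) == 0
        assert s.sd == pytest.approx(np.std(data, ddof=1))

    def test_outlier_beyond_four_iqr(self):
        from coswater.polfit import _summarize

        data = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 100.0])
        s = _summarize(data)
        assert 100.0 in s.outliers

    def test_identical_values_no_spread(self):
        from coswater.polfit import _summarize

        s = _summarize(np.full(10, 2.5))
        assert s.sd == 0.0 and len(s.outliers) == 0

    def test_noiseless_r2_is_one(self, noiseless_dataset):
        free, cons, stats = run_consensus_pipeline(noiseless_dataset, subset_size=5, seed=1)
        assert np.all(stats.r2_free > 1 - 1e-10)
        assert np.all(stats.r2_consensus > 1 - 1e-10)

    def test_inhomogeneity_lowers_free_r2_only(self, solute):
        # perturbed linear response: free fits scatter, consensus restores it
        from coswater.synthetic import NoiseSpec, generate_dataset

        ds = generate_dataset(
            40, solute, seed=77, noise=NoiseSpec(inhomogeneity=0.3),
            number_density=8.0, shell_outer=0.9,
        )
        free, cons, stats = run_consensus_pipeline(ds, subset_size=20, seed=2)
        assert np.all(stats.r2_consensus > stats.r2_free)


class TestChargeFit:
    def test_round_trip_recovery_and_constraint(self, ff):
        sites = ff.geometry.site_positions()[1:]
        grid = connolly_grid(
            ff.geometry.site_positions()[:3], ("O", "H", "H"), density=1.0
        )
        d = np.linalg.norm(grid[:, None, :] - sites[None, :, :], axis=-1)
        phi = F_ELEC * (np.array([ff.charges.q_H, ff.charges.q_H, ff.charges.q_M]) / d).sum(axis=1)
        fit = fit_static_charges(grid, phi, sites)
        assert fit.charges["H1"] == pytest.approx(0.539, abs=1e-10)
        assert fit.charges["H2"] == fit.charges["H1"]
        assert fit.charges["M"] == pytest.approx(-1.078, abs=1e-10)
        assert fit.constraint_residual <= 1e-12
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_net_charge_constraint_nonzero_target(self, ff, rng):
        sites = ff.geometry.site_positions()[1:]
        grid = connolly_grid(ff.geometry.site_positions()[:3], ("O", "H", "H"), density=0.5)
        phi = rng.normal(size=len(grid))
        fit = fit_static_charges(grid, phi, sites, net_charge=-1.0)
        assert sum(fit.charges.values()) == pytest.approx(-1.0, abs=1e-12)


class TestMSiteScan:
    def test_recovers_generating_offset_and_dipole(self, ff):
        geo = ff.geometry  # d_OM = 0.0225
        sites = geo.site_positions()[1:]
        grid = connolly_grid(geo.site_positions()[:3], ("O", "H", "H"), density=1.0)
        d = np.linalg.norm(grid[:, None, :] - sites[None, :, :], axis=-1)
        phi = F_ELEC * (np.array([ff.charges.q_H, ff.charges.q_H, ff.charges.q_M]) / d).sum(axis=1)
        scan = scan_msite(grid, phi, geo)
        assert scan.optimal_displacement == pytest.approx(0.0225, abs=1e-12)
        assert scan.rmsd[np.argmin(scan.rmsd)] <= scan.rmsd.min()
        assert np.all(scan.rmsd >= scan.rmsd.min())
        assert scan.optimal_dipole == pytest.approx(ff.static_dipole, abs=1e-3)

    def test_monotonicity_validation(self, ff):
        with pytest.raises(ValueError):
            scan_msite(np.zeros((10, 3)), np.zeros(10), ff.geometry, np.array([0.02, 0.01]))
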
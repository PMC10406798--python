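"""Band-space PCA: covariance, eigenstructure, PC images, reconstruction."""

import numpy as np
import pytest

from mstissue import (
    SpectralCube,
    WavelengthGrid,
    band_covariance,
    center_by_band_mean,
    compute_principal_components,
    decompose,
    eigendecompose,
    group_average_eigenvectors,
    reconstruct_cube,
    select_num_components,
    variance_percentages,
)

# The five published eigenvalues of the control group and their percentages
# as printed; the percentages use a total-variance denominator that includes
# eigenvalues beyond the five listed, so they cannot be recovered by
# normalizing the listed values alone.
CONTROL_EIGENVALUES = np.array([2.41, 0.25, 0.03, 0.02, 0.01])
CONTROL_PRINTED_PCT = np.array([88.08, 9.27, 1.25, 0.56, 0.33])


class TestCentering:
    def test_constant_band_centers_to_zero(self, small_grid):
        cube = SpectralCube(np.full((4, 4, 6), 3.0), small_grid, "absorbance")
        centered, mean = center_by_band_mean(cube)
        np.testing.assert_allclose(mean, 3.0)
        np.testing.assert_allclose(centered.data, 0.0, atol=1e-15)

    def test_adding_mean_back_recovers_input(self, random_absorbance_cube):
        centered, mean = center_by_band_mean(random_absorbance_cube)
        np.testing.assert_allclose(centered.data + mean,
                                   random_absorbance_cube.data, atol=1e-12)

    def test_band_means_vanish(self, random_absorbance_cube):
        centered, _ = center_by_band_mean(random_absorbance_cube)
        np.testing.assert_allclose(centered.data.mean(axis=(0, 1)), 0, atol=1e-10)


class TestBandCovariance:
    def test_zero_cube_gives_zero_matrix(self, small_grid):
        cube = SpectralCube(np.zeros((3, 3, 6)), small_grid, "absorbance")
        np.testing.assert_array_equal(band_covariance(cube), 0.0)

    def test_population_variance_of_plus_minus_one(self):
        grid = WavelengthGrid([500.0])
        data = np.array([[[-1.0]], [[1.0]]])  # two pixels, one band
        S = band_covariance(SpectralCube(data, grid, "absorbance"))
        np.testing.assert_allclose(S, [[1.0]])

    def test_matches_triple_loop_summation(self, rng):
        grid = WavelengthGrid([500.0, 550.0, 600.0])
        data = rng.normal(size=(6, 6, 3))
        data -= data.mean(axis=(0, 1))
        cube = SpectralCube(data, grid, "absorbance")
        S = band_covariance(cube)
        M = 36
        expected = np.zeros((3, 3))
        for l1 in range(3):
            for l2 in range(3):
                for r in range(6):
                    for c in range(6):
                        expected[l1, l2] += data[r, c, l1] * data[r, c, l2]
        np.testing.assert_allclose(S, expected / M, atol=1e-12)

    def test_symmetric_psd(self, random_absorbance_cube):
        centered, _ = center_by_band_mean(random_absorbance_cube)
        S = band_covariance(centered)
        np.testing.assert_allclose(S, S.T, atol=1e-14)
        assert np.linalg.eigvalsh(S).min() > -1e-12


class TestEigendecompose:
    def test_diagonal_case_with_sign_convention(self):
        evals, evecs = eigendecompose(np.diag([2.0, 1.0]))
        np.testing.assert_allclose(evals, [2.0, 1.0])
        np.testing.assert_allclose(evecs, np.eye(2), atol=1e-14)

    def test_trace_identity_and_reconstruction(self, rng):
        X = rng.normal(size=(40, 5))
        S = X.T @ X / 40
        evals, evecs = eigendecompose(S)
        assert abs(evals.sum() - np.trace(S)) < 1e-10
        np.testing.assert_allclose((evecs * evals) @ evecs.T, S, atol=1e-10)

    def test_orthonormal_columns(self, rng):
        X = rng.normal(size=(30, 6))
        _, evecs = eigendecompose(X.T @ X / 30)
        np.testing.assert_allclose(evecs.T @ evecs, np.eye(6), atol=1e-10)

    def test_eigenpairs_satisfy_the_eigenvalue_equation(self, rng):
        X = rng.normal(size=(50, 6))
        S = X.T @ X / 50
        evals, evecs = eigendecompose(S)
        for a in range(6):
            np.testing.assert_allclose(S @ evecs[:, a], evals[a] * evecs[:, a],
                                       atol=1e-8 * np.trace(S))

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestPrincipalComponents:
    def test_identity_eigenvectors_return_bands(self, random_absorbance_cube):
        centered, _ = center_by_band_mean(random_absorbance_cube)
        pcs = compute_principal_components(centered, np.eye(centered.n_bands))
        np.testing.assert_allclose(pcs, centered.data, atol=1e-14)

    def test_pc_images_are_zero_mean_and_uncorrelated(self, random_absorbance_cube):
        d = decompose(random_absorbance_cube)
        flat = d.pcs.reshape(-1, d.n_bands)
        np.testing.assert_allclose(flat.mean(axis=0), 0, atol=1e-10)
        cov = flat.T @ flat / flat.shape[0]
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * d.eigenvalues[0]

    def test_pc_variance_equals_eigenvalue(self, random_absorbance_cube):
        d = decompose(random_absorbance_cube)
        flat = d.pcs.reshape(-1, d.n_bands)
        np.testing.assert_allclose(flat.var(axis=0), d.eigenvalues,
                                   atol=1e-8 * d.eigenvalues[0])

    def test_dimension_mismatch(self, random_absorbance_cube):
        centered, _ = center_by_band_mean(random_absorbance_cube)
        with pytest.raises(ValueError):
            compute_principal_components(centered, np.eye(4))


class TestReconstruction:
    def test_full_rank_round_trip(self, rng):
        grid = WavelengthGrid([400.0, 450.0, 500.0, 550.0])
        cube = SpectralCube(rng.uniform(0.1, 1, size=(8, 8, 4)), grid, "absorbance")
        d = decompose(cube)
        recon = reconstruct_cube(d.pcs, d.eigenvectors, d.mean_spectrum)
        assert np.abs(recon - cube.data).max() < 1e-8

    def test_zero_components_give_the_mean_spectrum(self, random_absorbance_cube):
        d = decompose(random_absorbance_cube)
        recon = reconstruct_cube(d.pcs, d.eigenvectors, d.mean_spectrum,
                                 n_components=0)
        np.testing.assert_allclose(recon, np.broadcast_to(
            d.mean_spectrum, recon.shape), atol=1e-14)

    def test_rank1_cube_is_exact_with_one_component(self, rng):
        grid = WavelengthGrid([400.0, 500.0, 600.0])
        spectrum = np.array([1.0, 2.0, 3.0])
        weights = rng.uniform(0.1, 1, size=(6, 6))
        cube = SpectralCube(weights[:, :, None] * spectrum, grid, "absorbance")
        d = decompose(cube)
        recon = reconstruct_cube(d.pcs, d.eigenvectors, d.mean_spectrum,
                                 n_components=1)
        assert np.abs(recon - cube.data).max() < 1e-8

    def test_residual_variance_equals_dropped_eigenvalues(self, random_absorbance_cube):
        d = decompose(random_absorbance_cube)
        for m in range(d.n_bands):
            recon = reconstruct_cube(d.pcs, d.eigenvectors, d.mean_spectrum,
                                     n_components=m)
            resid = random_absorbance_cube.data - recon
            resid_var = (resid**2).reshape(-1, d.n_bands).sum(axis=1).mean()
            expected = d.eigenvalues[m:].sum()
            assert abs(resid_var - expected) <= 1e-6 * max(expected, 1e-12)

    def test_reconstruction_error_is_monotone_in_m(self, random_absorbance_cube):
        d = decompose(random_absorbance_cube)
        errs = []
        for m in range(d.n_bands + 1):
            recon = reconstruct_cube(d.pcs, d.eigenvectors, d.mean_spectrum,
                                     n_components=m)
            errs.append(((random_absorbance_cube.data - recon) ** 2).sum())
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))


class TestVarianceBookkeeping:
    def test_three_to_one_split(self):
        np.testing.assert_allclose(variance_percentages([3.0, 1.0]), [75.0, 25.0])

    def test_single_eigenvalue_is_everything(self):
        np.testing.assert_allclose(variance_percentages([0.7]), [100.0])

    def test_normalizing_the_five_published_control_eigenvalues(self):
        # frozen from the independent normalization 100*g/sum(g):
        pct = variance_percentages(CONTROL_EIGENVALUES)
        np.testing.assert_allclose(
            pct, [88.602941, 9.191176, 1.102941, 0.735294, 0.367647], atol=1e-6)
        assert abs(pct.sum() - 100) < 1e-8
        # ... which does NOT reproduce the printed percentages (larger
        # denominator in the published table):
        assert np.abs(pct - CONTROL_PRINTED_PCT).max() > 0.1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            variance_percentages([0.0, 0.0])

    def test_total_variance_conservation(self, random_absorbance_cube):
        centered, _ = center_by_band_mean(random_absorbance_cube)
        S = band_covariance(centered)
        d = decompose(random_absorbance_cube)
        band_vars = centered.valid_pixels().var(axis=0)
        assert abs(d.eigenvalues.sum() - np.trace(S)) < 1e-10
        assert abs(d.eigenvalues.sum() - band_vars.sum()) < 1e-10


class TestComponentSelection:
    def test_99pct_rule_on_published_control_percentages_selects_four(self):
        # cumulative: 88.08, 97.35, 98.60, 99.16 -> 4 (the published analysis
        # nevertheless fixed five components)
        assert select_num_components(CONTROL_PRINTED_PCT, threshold_pct=99) == 4

    def test_single_component_at_100pct(self):
        assert select_num_components(np.array([100.0]), threshold_pct=99) == 1

    def test_fixed_m_overrides_percentages(self):
        assert select_num_components(CONTROL_PRINTED_PCT, threshold_pct=99,
                                     fixed_m=5) == 5

    def test_unreachable_threshold(self):
        with pytest.raises(ValueError, match="reach"):
            select_num_components(np.array([50.0, 20.0]), threshold_pct=99)


class TestGroupAverageEigenvectors:
    def _decomp_with_vector(self, v, grid):
        from mstissue import EigenDecomposition
        n = len(v)
        evecs = np.eye(n)
        evecs[:, 0] = v
        return EigenDecomposition(
            mean_spectrum=np.zeros(n), eigenvalues=np.linspace(1, 0.1, n),
            eigenvectors=evecs, pcs=np.zeros((2, 2, n)),
            variance_pct=np.ones(n), grid=grid, mask=np.ones((2, 2), bool))

    def test_identical_individuals(self, small_grid):
        v = np.ones(6) / np.sqrt(6)
        ds = [self._decomp_with_vector(v, small_grid) for _ in range(4)]
        mean, std = group_average_eigenvectors(ds, 0)
        np.testing.assert_allclose(mean, v)
        np.testing.assert_allclose(std, 0, atol=1e-15)

    def test_sign_flip_is_aligned_before_averaging(self, small_grid):
        v = np.ones(6) / np.sqrt(6)
        ds = [self._decomp_with_vector(v, small_grid),
              self._decomp_with_vector(-v, small_grid)]
        mean, std = group_average_eigenvectors(ds, 0)
        np.testing.assert_allclose(mean, v)
        np.testing.assert_allclose(std, 0, atol=1e-15)

    def test_std_matches_explicit_loop(self, rng, small_grid):
        base = rng.normal(size=6)
        base /= np.linalg.norm(base)
        perturbed = []
        for _ in range(5):
            v = base + 0.05 * rng.normal(size=6)
            v /= np.linalg.norm(v)
            perturbed.append(v)
        ds = [self._decomp_with_vector(v, small_grid) for v in perturbed]
        mean, std = group_average_eigenvectors(ds, 0)
        stack = np.stack(perturbed)
        for b in range(6):
            mu = sum(stack[:, b]) / 5
            var = sum((stack[i, b] - mu) ** 2 for i in range(5)) / 5
            assert abs(mean[b] - mu) < 1e-12
            assert abs(std[b] - np.sqrt(var)) < 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_average_eigenvectors([], 0)


class TestNoiseFloor:
    def test_eigenvalues_beyond_signal_rank_sit_at_the_noise_level(self, rng):
        # cube = 2 independent spectra + iid noise: eigenvalues 3..N <= sigma^2*(1+tol)
        grid = WavelengthGrid([400.0, 450, 500, 550, 600])
        sigma = 0.01
        spectra = rng.uniform(0, 1, size=(2, 5))
        weights = rng.uniform(0, 1, size=(40, 40, 2))
        data = np.einsum("rcj,jb->rcb", weights, spectra)
        data += rng.normal(0, sigma, data.shape)
        d = decompose(SpectralCube(data, grid, "absorbance"))
        assert (d.eigenvalues[2:] <= sigma**2 * 1.5).all()
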
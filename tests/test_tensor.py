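import numpy as np
import pytest
from hypothesis import given, strategies as st

from dtiplast.geometry import default_affine
from dtiplast.schemes import AcquisitionScheme, SchemeError
from dtiplast.simulate import simulate_dwi
from dtiplast.tensor import (TensorField, compute_indices, design_matrix,
                             eigendecompose, fa_from_eigenvalues, fit_tensor,
                             index_maps_from_dwi, matrices_to_tensors, FitQC)


def _field_from_d6(d6_voxel, shape=(6, 6, 3), s0=1000.0):
    d6 = np.broadcast_to(np.asarray(d6_voxel), shape + (6,)).copy()
    return TensorField(d6=d6, s0=np.full(shape, s0),
                       voxel_size=(0.2, 0.2, 1.2),
                       affine=default_affine(shape, (0.2, 0.2, 1.2)))


class TestDesignMatrix:
    def test_b0_row_is_pure_intercept(self, scheme):
        X = design_matrix(scheme)
        np.testing.assert_array_equal(X[0], [1, 0, 0, 0, 0, 0, 0])

    def test_x_direction_row_by_formula(self):
        bvals = np.r_[0.0, np.full(6, 1000.0)]
        vecs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                         [1, 1, 0] / np.sqrt(2), [1, 0, 1] / np.sqrt(2),
                         [0, 1, 1] / np.sqrt(2)])
        X = design_matrix(AcquisitionScheme(bvals=bvals, bvecs=vecs))
        np.testing.assert_allclose(X[1], [1, -1000, 0, 0, 0, 0, 0])

    def test_coplanar_scheme_rejected(self):
        ang = np.linspace(0, np.pi, 7)[:6]
        vecs = np.vstack([np.zeros(3),
                          np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)])
        with pytest.raises(SchemeError, match="rank"):
            AcquisitionScheme(bvals=np.r_[0.0, np.full(6, 1000.0)], bvecs=vecs)


class TestFit:
    @pytest.mark.parametrize("method", ["ols", "wls"])
    def test_noise_free_roundtrip_recovers_tensor_elements(self, scheme, method, rng):
        # random SPD tensors: the forward-model inversion must be exact
        A = rng.normal(size=(6, 6, 3, 3, 3)) * 0.5e-3
        D = A @ np.swapaxes(A, -1, -2) + 0.2e-3 * np.eye(3)
        field = TensorField(d6=matrices_to_tensors(D),
                            s0=np.full((6, 6, 3), 800.0),
                            voxel_size=(0.2, 0.2, 1.2),
                            affine=default_affine((6, 6, 3), (0.2, 0.2, 1.2)))
        dwi = simulate_dwi(field, scheme, noise_sigma=0.0)
        fitted, _, _ = fit_tensor(dwi, method=method)
        np.testing.assert_allclose(fitted.d6, field.d6, rtol=1e-8, atol=1e-14)
        np.testing.assert_allclose(fitted.s0, 800.0, rtol=1e-10)

    def test_isotropic_closed_form_md(self, scheme):
        field = _field_from_d6([7e-4, 7e-4, 7e-4, 0, 0, 0])
        dwi = simulate_dwi(field, scheme, noise_sigma=0.0)
        maps, _ = index_maps_from_dwi(dwi)
        np.testing.assert_allclose(maps.md[np.isfinite(maps.md)], 7e-4, rtol=1e-10)

    def test_ols_and_wls_agree_on_noise_free_data(self, scheme):
        field = _field_from_d6([9e-4, 6e-4, 5e-4, 1e-4, 0, -0.5e-4])
        dwi = simulate_dwi(field, scheme, noise_sigma=0.0)
        ols, _, _ = fit_tensor(dwi, method="ols")
        wls, _, _ = fit_tensor(dwi, method="wls")
        np.testing.assert_allclose(ols.d6, wls.d6, rtol=1e-6, atol=1e-12)

    def test_wls_md_bias_small_under_rician_noise(self, scheme):
        """Median MD bias < 2% at SNR 25 over 500 voxels."""
        field = _field_from_d6([7e-4, 7e-4, 7e-4, 0, 0, 0], shape=(10, 10, 5))
        dwi = simulate_dwi(field, scheme, noise_sigma=1000.0 / 25.0, rng=3)
        maps, _ = index_maps_from_dwi(dwi, method="wls")
        md = maps.md[np.isfinite(maps.md)]
        assert abs(np.median(md) / 7e-4 - 1.0) < 0.02

    def test_all_nonpositive_voxel_invalidated_and_counted(self, scheme):
        field = _field_from_d6([7e-4, 7e-4, 7e-4, 0, 0, 0], shape=(4, 4, 2))
        dwi = simulate_dwi(field, scheme, noise_sigma=0.0)
        dwi.data[0, 0, 0, :] = -1.0
        _, mask_out, qc = fit_tensor(dwi)
        assert not mask_out[0, 0, 0]
        assert qc.n_invalid == 1

    def test_nonpositive_samples_clamped_not_fatal(self, scheme):
        field = _field_from_d6([7e-4, 7e-4, 7e-4, 0, 0, 0], shape=(4, 4, 2))
        dwi = simulate_dwi(field, scheme, noise_sigma=0.0)
        dwi.data[1, 1, 1, 5] = 0.0
        _, mask_out, qc = fit_tensor(dwi)
        assert mask_out[1, 1, 1]
        assert qc.n_clamped_signals == 1


class TestEigenIndices:
    def test_sorting_and_zero_tensor(self):
        d6 = np.zeros((2, 1, 1, 6))
        d6[0, 0, 0] = [3e-3, 1e-3, 2e-3, 0, 0, 0]
        evals, _, _ = eigendecompose(d6)
        np.testing.assert_allclose(evals[0, 0, 0], [3e-3, 2e-3, 1e-3])
        np.testing.assert_array_equal(evals[1, 0, 0], 0.0)

    def test_negative_eigenvalues_clamped_and_counted(self):
        d6 = np.array([[[[-1e-3, -1e-3, -1e-3, 0, 0, 0]]]])
        qc = FitQC()
        evals, _, _ = eigendecompose(d6, qc=qc)
        assert np.all(evals >= 0)
        assert qc.n_negative_eigenvalues == 3

    def test_nonfinite_voxel_invalidated(self):
        d6 = np.zeros((2, 1, 1, 6))
        d6[1, 0, 0, 0] = np.nan
        _, _, mask = eigendecompose(d6)
        assert mask[0, 0, 0] and not mask[1, 0, 0]

    @given(st.integers(0, 2**31 - 1))
    def test_reconstruction_matches_input(self, seed):
        """V diag(w) V^T reproduces any SPD input within 1e-10."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3)) * 1e-3
        D = A @ A.T + 1e-4 * np.eye(3)          # SPD: no clamping involved
        d6 = matrices_to_tensors(D)[None, None, None]
        evals, evecs, _ = eigendecompose(d6)
        V = evecs[0, 0, 0]
        rec = V @ np.diag(evals[0, 0, 0]) @ V.T
        np.testing.assert_allclose(rec, D, atol=1e-10)

    def test_isotropic_indices(self):
        evals = np.array([[[[1e-3, 1e-3, 1e-3]]]])
        maps = compute_indices(evals, np.ones((1, 1, 1), bool), (0.2, 0.2, 1.2),
                               np.eye(4))
        assert maps.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert maps.md[0, 0, 0] == pytest.approx(1e-3)
        assert maps.ad[0, 0, 0] == pytest.approx(1e-3)
        assert maps.rd[0, 0, 0] == pytest.approx(1e-3)

    def test_stick_limit_fa_is_one(self):
        assert fa_from_eigenvalues([2e-3, 0, 0]) == pytest.approx(1.0)

    def test_reference_triple_frozen_values(self):
        # independent evaluation of the FA formula:
        # FA(1.7, 0.3, 0.2 um^2/ms) = 0.8358681096, MD = 0.73333e-3, RD = 0.25e-3
        evals = np.array([[[[1.7e-3, 0.3e-3, 0.2e-3]]]])
        maps = compute_indices(evals, np.ones((1, 1, 1), bool), (0.2, 0.2, 1.2),
                               np.eye(4))
        assert maps.fa[0, 0, 0] == pytest.approx(0.8358681096, abs=1e-9)
        assert maps.md[0, 0, 0] == pytest.approx(0.7333333333e-3, rel=1e-9)
        assert maps.rd[0, 0, 0] == pytest.approx(0.25e-3, rel=1e-12)

    def test_unsorted_eigenvalues_rejected(self):
        evals = np.array([[[[0.2e-3, 0.3e-3, 1.7e-3]]]])
        with pytest.raises(ValueError, match="sorted"):
            compute_indices(evals, np.ones((1, 1, 1), bool), (0.2, 0.2, 1.2),
                            np.eye(4))

    @given(st.floats(0.1, 10.0))
    def test_fa_scale_invariance(self, scale):
        ev = np.array([1.3e-3, 0.5e-3, 0.4e-3])
        assert fa_from_eigenvalues(ev) == pytest.approx(
            fa_from_eigenvalues(ev * scale), rel=1e-12)


def test_md_identity_holds_on_fitted_maps(phantom, scheme):
    """MD == (AD + 2 RD)/3 at every fitted voxel."""
    spec, field, rois, mask = phantom
    dwi = simulate_dwi(field, scheme, noise_sigma=spec.s0 / 40, rng=9)
    maps, _ = index_maps_from_dwi(dwi, mask)
    lhs, rhs = maps.md[maps.mask], (maps.ad + 2 * maps.rd)[maps.mask] / 3
    np.testing.assert_allclose(lhs, rhs, rtol=1e-12)
    assert np.all((maps.fa[maps.mask] >= 0) & (maps.fa[maps.mask] <= 1))
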
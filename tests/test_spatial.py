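import numpy as np
import pytest

from dtiplast.geometry import default_affine
from dtiplast.experiments import _blob_image
from dtiplast.phantom import build_phantom, default_phantom_spec
from dtiplast.spatial import (DegenerateFitError, Transform, apply_transform,
                              bias_correct, gaussian_smooth, normalization_qa,
                              qa_sd_ratio, register)

VS = (0.2, 0.2, 1.2)


def _scene(shape=(32, 32, 8), seed=4):
    affine = default_affine(shape, VS)
    rng = np.random.default_rng(seed)
    f = _blob_image(shape, affine, rng, voxel_size=VS)
    ii = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                  axis=-1)
    world = ii @ affine[:3, :3].T + affine[:3, 3]
    return affine, world, f


class TestBiasCorrect:
    def test_unbiased_input_gives_unit_field(self, phantom):
        spec, field, rois, mask = phantom
        b0 = np.where(mask, spec.s0, 0.0)
        corrected, est = bias_correct(b0, mask)
        assert np.abs(est[mask] - 1.0).max() < 0.01
        np.testing.assert_allclose(corrected[mask], spec.s0, rtol=0.01)

    def test_linear_ramp_removed(self, phantom):
        """A 15% ramp raises the in-mask CV; correction cuts it >= 5x."""
        spec, field, rois, mask = phantom
        nx = spec.shape[1]
        ramp = 1.0 - 0.15 * (np.arange(nx) / (nx - 1))[None, :, None]
        biased = np.where(mask, spec.s0 * ramp, 0.0)
        corrected, _ = bias_correct(biased, mask)
        cv = lambda v: v[mask].std() / v[mask].mean()
        assert cv(biased) / cv(corrected) >= 5.0
        # in-mask mean unchanged by the correction
        assert corrected[mask].mean() == pytest.approx(biased[mask].mean())

    def test_tiny_mask_degenerate(self):
        vol = np.ones((8, 8, 4))
        mask = np.zeros((8, 8, 4), bool)
        mask[2, 2, 1] = mask[3, 3, 1] = mask[4, 4, 2] = True
        with pytest.raises(DegenerateFitError):
            bias_correct(vol, mask)


class TestRegister:
    def test_identity_when_images_match(self):
        affine, world, f = _scene()
        img = f(world)
        T = register(img, img, affine, affine, kind="rigid-6", voxel_size=VS)
        assert np.abs(T.matrix - np.eye(4)).max() < 0.02

    def test_known_translation_recovered_within_tenth_voxel(self):
        affine, world, f = _scene(seed=6)
        fixed = f(world)
        T_true = Transform.rigid(translation=(1.0, -0.6, 0.0))
        moving = f(world @ T_true.matrix[:3, :3].T + T_true.matrix[:3, 3])
        T = register(moving, fixed, affine, affine, kind="rigid-6",
                     voxel_size=VS)
        err = np.abs(T.matrix[:3, 3] - (1.0, -0.6, 0.0))
        assert err[0] <= 0.02 and err[1] <= 0.02     # 0.1 in-plane voxel

    def test_affine_recovers_anisotropic_scale(self):
        affine, world, f = _scene(seed=7)
        fixed = f(world)
        T_true = Transform.affine12(translation=(0.3, -0.2, 0.0),
                                    rotation_deg=(0, 0, 2), scale=(1.05, 1, 1))
        moving = f(world @ T_true.matrix[:3, :3].T + T_true.matrix[:3, 3])
        T = register(moving, fixed, affine, affine, kind="affine-12",
                     voxel_size=VS)
        sx = np.linalg.norm(T.matrix[:3, 0])
        assert sx == pytest.approx(1.05, abs=0.005)


class TestTransform:
    def test_rigid_block_validated(self):
        M = np.eye(4)
        M[0, 0] = 2.0
        with pytest.raises(ValueError, match="orthonormal"):
            Transform(kind="rigid-6", matrix=M)

    def test_save_load_roundtrip(self, tmp_path):
        T = Transform.affine12(translation=(1, 2, 3), rotation_deg=(1, 0, 5),
                               scale=(1.02, 0.98, 1.0), shear=(0.01, 0, 0))
        T.save(tmp_path / "t.txt")
        R = Transform.load(tmp_path / "t.txt")
        assert R.kind == "affine-12"
        np.testing.assert_allclose(R.matrix, T.matrix, atol=1e-10)

    def test_composition_is_associative(self):
        A = Transform.rigid(translation=(1, 0, 0), rotation_deg=(0, 0, 5))
        B = Transform.rigid(translation=(0, 1, 0), rotation_deg=(2, 0, 0))
        C = Transform.rigid(translation=(0, 0, 1))
        lhs = A.compose(B).compose(C)
        rhs = A.compose(B.compose(C))
        np.testing.assert_allclose(lhs.matrix, rhs.matrix, atol=1e-12)


class TestApplyTransform:
    def test_identity_chain_bit_identical(self, phantom):
        spec, field, rois, mask = phantom
        arr = np.where(mask, 1.7, np.nan)
        out = apply_transform(arr, spec.affine, Transform.identity(),
                              spec.affine, spec.shape)
        np.testing.assert_array_equal(out, arr)

    def test_integer_voxel_translation_exact_shift(self, phantom):
        spec, field, rois, mask = phantom
        arr = np.asarray(rois.data, dtype=float)
        T = Transform.rigid(translation=(2 * spec.voxel_size[0], 0, 0))
        out = apply_transform(arr, spec.affine, T, spec.affine, spec.shape)
        np.testing.assert_array_equal(out[2:, :, :], arr[:-2, :, :])
        assert np.all(np.isnan(out[:2]))

    def test_nearest_preserves_binary_values(self, phantom):
        spec, field, rois, mask = phantom
        T = Transform.rigid(translation=(0.13, -0.07, 0.2),
                            rotation_deg=(0, 0, 3))
        out = apply_transform(mask.astype(np.uint8), spec.affine, T,
                              spec.affine, spec.shape)
        assert set(np.unique(out)) <= {0, 1}

    def test_composed_equals_sequential_within_one_lattice_step(self):
        affine, world, f = _scene(shape=(24, 24, 6), seed=9)
        img = f(world)
        A = Transform.rigid(translation=(0.45, -0.3, 0), rotation_deg=(0, 0, 4))
        B = Transform.rigid(translation=(-0.2, 0.15, 0), rotation_deg=(0, 0, -2))
        once = apply_transform(img, affine, A.compose(B), affine, img.shape,
                               interpolation="trilinear")
        twice = apply_transform(
            apply_transform(img, affine, B, affine, img.shape,
                            interpolation="trilinear"),
            affine, A, affine, img.shape, interpolation="trilinear")
        both = np.isfinite(once) & np.isfinite(twice)
        # one extra interpolation: differences bounded by a lattice-step of
        # the image's variation
        step = np.abs(np.diff(img, axis=0)).max()
        assert np.abs(once[both] - twice[both]).max() <= step


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        arr = rng.normal(size=(8, 8, 4))
        np.testing.assert_array_equal(gaussian_smooth(arr, VS, fwhm=0.0), arr)

    def test_impulse_mass_preserved(self):
        arr = np.zeros((17, 17, 5))
        arr[8, 8, 2] = 1.0
        out = gaussian_smooth(arr, VS, fwhm=0.3)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_map_unchanged_and_nan_respected(self, phantom):
        spec, field, rois, mask = phantom
        arr = np.where(mask, 4.2, np.nan)
        out = gaussian_smooth(arr, VS, fwhm=0.3)
        np.testing.assert_allclose(out[mask], 4.2, rtol=1e-6)
        assert np.all(np.isnan(out[~mask]))

    def test_range_never_widens(self, rng):
        arr = rng.normal(size=(12, 12, 4))
        out = gaussian_smooth(arr, VS, fwhm=0.5)
        assert out.min() >= arr.min() - 1e-12
        assert out.max() <= arr.max() + 1e-12


class TestNormalizationQA:
    def test_identical_maps_zero_sd(self, rng):
        m = rng.normal(size=(10, 10, 3))
        mean, sd, cv = normalization_qa([m, m.copy(), m.copy()])
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_single_map_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            normalization_qa([rng.normal(size=(4, 4, 2))])

    def test_affine_normalization_beats_rigid_only(self):
        """Residual anatomical SD drops when the scale mismatch is removed."""
        spec = default_phantom_spec((32, 32, 4))
        field, rois, mask = build_phantom(spec)
        from dtiplast.tensor import index_maps_from_field
        template = np.nan_to_num(index_maps_from_field(field, mask).fa)
        rng = np.random.default_rng(2)
        rigid_only, full = [], []
        for k in range(4):
            T_true = Transform.affine12(
                translation=rng.uniform(-0.3, 0.3, 3) * [1, 1, 0],
                rotation_deg=(0, 0, rng.uniform(-4, 4)),
                scale=(rng.uniform(1.06, 1.12), rng.uniform(0.88, 0.94), 1.0))
            subject = apply_transform(template, spec.affine, T_true.inverse(),
                                      spec.affine, spec.shape,
                                      interpolation="trilinear", cval=0.0)
            for kind, dest in (("rigid-6", rigid_only), ("affine-12", full)):
                T = register(subject, template, spec.affine, spec.affine,
                             kind=kind, voxel_size=spec.voxel_size)
                dest.append(apply_transform(subject, spec.affine, T,
                                            spec.affine, spec.shape,
                                            interpolation="nearest"))
        ratio = qa_sd_ratio(full, rigid_only, mask)
        assert ratio < 1.0
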
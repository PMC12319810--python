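"""Preprocessing: stripping, bias removal, alignment, z-score, crop/pad."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from neuroage.errors import ConfigError, DegenerateInputError, DomainError, ShapeError
from neuroage.phantom import PhantomSpec, generate_phantom
from neuroage.preprocess import (
    PreprocessConfig,
    crop_pad,
    preprocess_volume,
    remove_bias_field,
    rigid_align,
    strip_with_mask,
    zscore_nonzero,
)


class TestStripWithMask:
    def test_all_ones_mask_is_identity(self):
        vol = np.random.default_rng(0).random((8, 8, 8))
        np.testing.assert_array_equal(
            strip_with_mask(vol, np.ones_like(vol)), vol
        )

    def test_all_zeros_mask_zeroes_volume(self):
        vol = np.random.default_rng(0).random((8, 8, 8))
        assert strip_with_mask(vol, np.zeros_like(vol)).sum() == 0

    def test_half_plane_mask_voxel_count(self):
        vol = np.random.default_rng(1).random((10, 10, 10)) + 0.1  # all nonzero
        mask = np.zeros_like(vol, dtype=bool)
        mask[:5] = True
        stripped = strip_with_mask(vol, mask)
        assert np.count_nonzero(stripped) == np.count_nonzero(mask & (vol != 0))

    def test_grid_mismatch_raises(self):
        with pytest.raises(ShapeError):
            strip_with_mask(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)))


class TestRemoveBiasField:
    def test_order_zero_is_global_rescale_only(self, spec32):
        vol = generate_phantom(40.0, seed=1, spec=spec32).data.astype(float)
        out = remove_bias_field(vol, order=0)
        np.testing.assert_allclose(out, vol, rtol=1e-12)

    def test_field_free_volume_nearly_unchanged(self, spec32):
        vol = generate_phantom(40.0, seed=3, spec=spec32).data.astype(float)
        out = remove_bias_field(vol, order=2)
        nz = vol > 0
        rms = np.sqrt(np.mean(((out[nz] - vol[nz]) / vol[nz].mean()) ** 2))
        assert rms < 0.02

    def test_linear_ramp_mostly_removed(self, spec32):
        vol = generate_phantom(40.0, seed=3, spec=spec32).data.astype(float)
        ramp = np.linspace(0.7, 1.3, vol.shape[0])[:, None, None]
        out = remove_bias_field(vol * ramp, order=2)
        nz = vol > 0
        ratio = out[nz] / vol[nz]
        x = np.nonzero(vol)[0].astype(float)
        design = np.stack([np.ones_like(x), x], axis=1)
        coef, *_ = np.linalg.lstsq(design, ratio, rcond=None)
        fitted = design @ coef
        rms_after = np.sqrt(np.mean((fitted - fitted.mean()) ** 2))
        ramp_vals = (ramp * np.ones_like(vol))[nz]
        rms_before = np.sqrt(np.mean((ramp_vals - ramp_vals.mean()) ** 2))
        assert rms_after < 0.2 * rms_before

    def test_mean_preserved_and_nonnegative(self, spec32):
        vol = generate_phantom(60.0, seed=2, spec=spec32).data.astype(float)
        out = remove_bias_field(vol, order=3)
        nz = vol > 0
        assert out.min() >= 0
        assert out[nz].mean() == pytest.approx(vol[nz].mean(), rel=1e-9)

    def test_all_zero_volume_raises(self):
        with pytest.raises(DomainError):
            remove_bias_field(np.zeros((8, 8, 8)))


class TestRigidAlign:
    def test_self_alignment_recovers_identity(self, spec32_clean):
        vol = generate_phantom(40.0, seed=3, spec=spec32_clean).data.astype(float)
        _, tr = rigid_align(vol, vol)
        assert np.abs(tr.translation_vox).max() < 0.5
        assert tr.rotation_angle_deg < 0.5

    def test_translation_recovered(self):
        spec = PhantomSpec(grid_dims=(64, 64, 64), noise_sd=0.0)
        vol = generate_phantom(40.0, seed=3, spec=spec).data.astype(float)
        shifted = ndimage.shift(vol, (0, 0, 5.0), order=1, cval=0.0)
        _, tr = rigid_align(shifted, vol)
        assert tr.translation_vox[2] == pytest.approx(5.0, abs=1.0)

    def test_rotation_recovered(self):
        spec = PhantomSpec(grid_dims=(64, 64, 64), noise_sd=0.0)
        vol = generate_phantom(40.0, seed=3, spec=spec).data.astype(float)
        ang = np.deg2rad(5.0)
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0],
                [np.sin(ang), np.cos(ang), 0],
                [0, 0, 1],
            ]
        )
        center = (np.array(vol.shape) - 1) / 2
        moved = ndimage.affine_transform(
            vol, rot, offset=center - rot @ center, order=1
        )
        _, tr = rigid_align(moved, vol)
        assert tr.rotation_angle_deg == pytest.approx(5.0, abs=1.5)

    def test_empty_foreground_raises(self):
        with pytest.raises(DomainError):
            rigid_align(np.zeros((16, 16, 16)), np.ones((16, 16, 16)))


class TestZscoreNonzero:
    def test_hand_computed_example(self):
        vol = np.zeros((3, 1, 1))
        vol[:, 0, 0] = [2.0, 4.0, 6.0]
        out = zscore_nonzero(vol)
        expected = np.array([-1.224745, 0.0, 1.224745])  # population sd
        np.testing.assert_allclose(out[:, 0, 0], expected, atol=1e-6)

    def test_zero_voxels_stay_zero_and_moments(self, spec32):
        vol = generate_phantom(30.0, seed=0, spec=spec32).data.astype(float)
        out = zscore_nonzero(vol)
        nz = vol != 0
        assert np.all(out[~nz] == 0.0)
        assert abs(out[nz].mean()) < 1e-6
        assert abs(out[nz].std() - 1.0) < 1e-6

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_on_continuous_data(self, seed):
        rng = np.random.default_rng(seed)
        vol = np.zeros((6, 6, 6))
        mask = rng.random(vol.shape) < 0.5
        mask.flat[:2] = True  # guarantee at least two voxels
        vol[mask] = rng.normal(10.0, 3.0, size=int(mask.sum()))
        once = zscore_nonzero(vol)
        twice = zscore_nonzero(once)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_all_background_raises(self):
        with pytest.raises(DegenerateInputError):
            zscore_nonzero(np.zeros((4, 4, 4)))

    def test_constant_foreground_raises(self):
        vol = np.zeros((4, 4, 4))
        vol[:2] = 3.0
        with pytest.raises(DegenerateInputError):
            zscore_nonzero(vol)


class TestCropPad:
    def test_identity_when_already_target_and_centered(self):
        vol = np.zeros((16, 20, 16))
        vol[6:10, 8:12, 6:10] = 1.0
        out = crop_pad(vol, (16, 20, 16))
        np.testing.assert_array_equal(out, vol)

    def test_mixed_pad_and_crop_dims_and_offsets(self):
        vol = np.ones((130, 210, 150))
        out = crop_pad(vol, (160, 192, 160))
        assert out.shape == (160, 192, 160)
        # axis 0: padded 130 -> 160, content centered at offset 15
        assert np.all(out[15:145, 96, 80] == 1.0)
        assert out[14, 96, 80] == 0.0 and out[145, 96, 80] == 0.0
        # axis 1: center-cropped 210 -> 192, so fully occupied
        assert np.all(out[80, :, 80] == 1.0)

    def test_all_zero_input(self):
        out = crop_pad(np.zeros((10, 10, 10)), (16, 16, 16))
        assert out.shape == (16, 16, 16)
        assert out.sum() == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_foreground_conserved_when_it_fits(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(8, 40, size=3))
        vol = np.zeros(shape)
        lo = [rng.integers(0, s - 4) for s in shape]
        sl = tuple(slice(l, l + 4) for l in lo)
        vol[sl] = rng.random((4, 4, 4)) + 0.5
        out = crop_pad(vol, (48, 48, 48))
        assert np.count_nonzero(out) == np.count_nonzero(vol)
        assert out.shape == (48, 48, 48)


class TestPipeline:
    def test_composition_contract(self, spec32):
        vol = generate_phantom(55.0, seed=9, spec=spec32).data.astype(float)
        mask = vol > 0
        config = PreprocessConfig(target_dims=(48, 48, 48))
        out = preprocess_volume(vol, brain_mask=mask, template=vol, config=config)
        assert out.shape == (48, 48, 48)
        assert np.all(np.isfinite(out))
        # background stayed zero through the chain
        assert np.count_nonzero(out) < out.size

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(target_dims=(0, 10, 10))
        with pytest.raises(ConfigError):
            PreprocessConfig(registration_mode="affine9")
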
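"""Windowing, cropping, resampling and CLAHE behaviour."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbctomics.preprocess import (
    PreprocessConfig,
    clahe_enhance,
    crop_to_foreground,
    preprocess_case,
    resample_to_shape,
    window_hu,
    _tile_mappings,
)
from cbctomics.volumes import MaskVolume, Volume


class TestWindow:
    @pytest.mark.parametrize(
        "value,expected", [(-500.0, -200.0), (50.0, 50.0), (1000.0, 300.0)]
    )
    def test_clamping(self, value, expected):
        v = Volume(data=np.full((2, 2, 2), value))
        assert window_hu(v, -200, 300).data[0, 0, 0] == expected

    def test_idempotent(self, rng):
        v = Volume(data=rng.normal(0, 400, size=(6, 6, 6)))
        w1 = window_hu(v, -200, 300)
        w2 = window_hu(w1, -200, 300)
        np.testing.assert_array_equal(w1.data, w2.data)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            window_hu(Volume(data=np.zeros((2, 2, 2))), 300, -200)


def _brute_bbox(fg):
    """Oracle: exhaustive scan for the tight bounding box."""
    lo, hi = [], []
    for ax in range(3):
        idx = [k for k in range(fg.shape[ax]) if np.take(fg, k, axis=ax).any()]
        lo.append(min(idx))
        hi.append(max(idx) + 1)
    return tuple(lo), tuple(hi)


class TestCrop:
    def test_block_bbox_matches_bruteforce(self, rng):
        for trial in range(5):
            data = np.full((20, 18, 16), -200.0)
            lo = rng.integers(0, 8, size=3)
            data[lo[0]:lo[0] + 8, lo[1]:lo[1] + 8, lo[2]:lo[2] + 8] = 50.0
            v = Volume(data=data)
            margin = int(rng.integers(0, 3))
            _, _, box = crop_to_foreground(v, margin=margin)
            blo, bhi = _brute_bbox(data > -200.0)
            exp_lo = tuple(max(b - margin, 0) for b in blo)
            exp_hi = tuple(min(b + margin, n) for b, n in zip(bhi, data.shape))
            assert box.lo == exp_lo and box.hi == exp_hi

    def test_margin_clipped_to_grid(self):
        data = np.full((10, 10, 10), -200.0)
        data[0:3, 0:3, 0:3] = 10.0
        _, _, box = crop_to_foreground(Volume(data=data), margin=100)
        assert box.lo == (0, 0, 0) and box.hi == (10, 10, 10)

    def test_mask_guided_crop_keeps_all_mask_voxels(self, rng):
        data = rng.normal(0, 50, size=(16, 16, 16))
        mask = MaskVolume(data=(rng.random((16, 16, 16)) > 0.9).astype(np.uint8))
        _, mc, _ = crop_to_foreground(Volume(data=data), mask, margin=1)
        assert mc.voxel_count == mask.voxel_count

    def test_empty_foreground_rejected(self):
        v = Volume(data=np.full((4, 4, 4), -200.0))
        with pytest.raises(ValueError, match="foreground"):
            crop_to_foreground(v)


class TestResample:
    def test_identity(self, small_volume):
        out = resample_to_shape(small_volume, small_volume.shape)
        np.testing.assert_array_equal(out.data, small_volume.data)

    def test_constant_preserved(self):
        v = Volume(data=np.full((8, 6, 4), 42.0))
        out = resample_to_shape(v, (13, 5, 9))
        np.testing.assert_allclose(out.data, 42.0, rtol=1e-12)

    def test_target_shape_and_extent(self, small_volume):
        out = resample_to_shape(small_volume, (24, 20, 16))
        assert out.shape == (24, 20, 16)
        for sp_new, n_new, sp_old, n_old in zip(
            out.spacing, out.shape, small_volume.spacing, small_volume.shape
        ):
            assert sp_new * n_new == pytest.approx(sp_old * n_old)

    def test_nearest_mode_for_masks(self, rng):
        m = MaskVolume(data=(rng.random((8, 8, 8)) > 0.5).astype(np.uint8))
        out = resample_to_shape(m, (12, 12, 12), mode="nearest")
        assert set(np.unique(out.data)) <= {0, 1}

    def test_bad_shape_rejected(self, small_volume):
        with pytest.raises(ValueError):
            resample_to_shape(small_volume, (0, 4, 4))


def _cfg(**kw):
    defaults = dict(target_shape=(16, 16, 8), clahe_tile_grid=(2, 2), clahe_n_bins=64)
    defaults.update(kw)
    return PreprocessConfig(**defaults)


class TestClahe:
    def test_constant_slice_maps_to_constant(self):
        v = Volume(data=np.full((16, 16, 4), 100.0))
        out = clahe_enhance(v, _cfg())
        for k in range(4):
            assert out.data[:, :, k].std() == 0.0

    def test_output_stays_in_window(self, rng):
        data = np.clip(rng.normal(50, 120, size=(32, 32, 4)), -200, 300)
        out = clahe_enhance(Volume(data=data), _cfg())
        assert out.data.min() >= -200 - 1e-9
        assert out.data.max() <= 300 + 1e-9

    def test_two_cluster_slice_contrast_increases(self, rng):
        # left tile near 0 HU, right tile near 200 HU, tight clusters
        data = np.empty((32, 32, 1))
        data[:16] = rng.normal(0.0, 3.0, size=(16, 32, 1))
        data[16:] = rng.normal(200.0, 3.0, size=(16, 32, 1))
        data = np.clip(data, -200, 300)
        v = Volume(data=data)
        out = clahe_enhance(v, _cfg(clahe_tile_grid=(2, 1)))
        for half in (slice(0, 16), slice(16, 32)):
            before = np.percentile(data[half], 95) - np.percentile(data[half], 5)
            after = np.percentile(out.data[half], 95) - np.percentile(out.data[half], 5)
            assert after > before

    def test_tile_mappings_monotone(self, rng):
        u = rng.random((32, 32))
        maps, _, _ = _tile_mappings(u, _cfg())
        assert (np.diff(maps, axis=-1) >= -1e-12).all()

    def test_tile_grid_larger_than_slice_rejected(self):
        v = Volume(data=np.zeros((4, 4, 2)))
        with pytest.raises(ValueError, match="tile grid"):
            clahe_enhance(v, _cfg(clahe_tile_grid=(8, 8)))


class TestPreprocessCase:
    def test_output_shape_and_composition(self, rng):
        data = rng.normal(30, 10, size=(40, 40, 20))
        data[10:30, 10:30, 5:15] += 60
        v = Volume(data=data, spacing=(1, 1, 5))
        mask = MaskVolume(
            data=(data > 60).astype(np.uint8), spacing=(1, 1, 5)
        )
        cfg = _cfg(target_shape=(32, 32, 16))
        out, mout = preprocess_case(v, mask, cfg)
        assert out.shape == (32, 32, 16)
        assert mout.shape == (32, 32, 16)

        cfg_off = _cfg(target_shape=(32, 32, 16), clahe_enabled=False)
        out2, _ = preprocess_case(v, mask, cfg_off)
        from cbctomics.preprocess import crop_to_foreground as crop

        vw = window_hu(v, *cfg.hu_window)
        vc, mc, _ = crop(vw, mask, margin=cfg.crop_margin)
        vr = resample_to_shape(vc, cfg.target_shape)
        np.testing.assert_allclose(out2.data, vr.data)

    def test_mask_count_changes_only_by_resampling(self, rng):
        data = rng.normal(30, 10, size=(24, 24, 12))
        mask = np.zeros_like(data, dtype=np.uint8)
        mask[6:18, 6:18, 3:9] = 1
        v = Volume(data=data, spacing=(1, 1, 5))
        m = MaskVolume(data=mask, spacing=(1, 1, 5))
        cfg = _cfg(target_shape=(24, 24, 12), crop_mode="intensity", crop_margin=0)
        _, mout = preprocess_case(v, m, cfg)
        # same grid, no crop loss: the count is exactly preserved
        assert mout.voxel_count == m.voxel_count

    def test_full_chain_deterministic(self, rng):
        data = rng.normal(30, 40, size=(32, 32, 8))
        v = Volume(data=data)
        cfg = _cfg()
        a, _ = preprocess_case(v, None, cfg)
        b, _ = preprocess_case(v, None, cfg)
        np.testing.assert_array_equal(a.data, b.data)
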
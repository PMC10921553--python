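"""Radiomics engine: discretization, first-order, shape and manifest."""
import numpy as np
import pytest
from scipy import stats

from cbctomics.radiomics import default_manifest, extract_features
from cbctomics.radiomics.discretize import discretize, discretize_array
from cbctomics.radiomics.firstorder import firstorder_features
from cbctomics.radiomics.manifest import (
    FIRSTORDER_NAMES,
    SHAPE_NAMES,
    FeatureManifest,
)
from cbctomics.radiomics.shape import shape_features
from cbctomics.volumes import MaskVolume, Volume

from conftest import make_ball_mask


class TestDiscretize:
    def test_worked_example(self):
        # {0, 24.9, 25, 50} at width 25 -> levels {1, 1, 2, 3}
        data = np.array([[[0.0, 24.9, 25.0, 50.0]]])
        d = discretize_array(data, np.ones_like(data, bool), 25.0)
        assert list(d.labels.ravel()) == [1, 1, 2, 3]
        assert d.n_levels == 3

    def test_constant_roi_single_level(self):
        data = np.full((3, 3, 3), 7.0)
        d = discretize_array(data, np.ones_like(data, bool), 25.0)
        assert d.n_levels == 1

    def test_shift_invariance(self, rng):
        data = rng.normal(0, 50, size=(5, 5, 5))
        mask = np.ones_like(data, bool)
        a = discretize_array(data, mask, 10.0)
        b = discretize_array(data + 123.456, mask, 10.0)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            discretize_array(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool), 25.0)


class TestFirstOrder:
    def test_energy_worked_example(self):
        data = np.array([[[1.0, 2.0, 3.0]]])
        f = firstorder_features(data, np.ones_like(data, bool), (1, 1, 1))
        assert f["Energy"] == pytest.approx(14.0)  # 1 + 4 + 9

    def test_constant_roi_degenerate_values(self):
        data = np.full((2, 2, 2), 5.0)
        f = firstorder_features(data, np.ones_like(data, bool), (1, 1, 1))
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0

    def test_symmetric_sample_zero_skewness(self):
        data = np.array([[[1.0, 2.0, 3.0, 4.0, 5.0]]])
        f = firstorder_features(data, np.ones_like(data, bool), (1, 1, 1))
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_moments_match_scipy(self, rng):
        data = rng.normal(10, 5, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.3
        f = firstorder_features(data, mask, (1, 1, 1))
        x = data[mask]
        assert f["Skewness"] == pytest.approx(stats.skew(x, bias=True))
        assert f["Kurtosis"] == pytest.approx(stats.kurtosis(x, bias=True, fisher=False))
        assert f["Variance"] == pytest.approx(np.var(x))

    def test_total_energy_scales_with_voxel_volume(self, rng):
        data = rng.random((3, 3, 3))
        mask = np.ones_like(data, bool)
        f1 = firstorder_features(data, mask, (1, 1, 1))
        f2 = firstorder_features(data, mask, (1, 1, 5))
        assert f2["TotalEnergy"] == pytest.approx(5 * f1["TotalEnergy"])
        assert f2["Energy"] == pytest.approx(f1["Energy"])


class TestShape:
    def test_single_voxel_volume(self):
        m = MaskVolume(data=np.pad(np.ones((1, 1, 1), np.uint8), 1))
        f = shape_features(m)
        assert f["VoxelVolume"] == pytest.approx(1.0)
        assert f["Maximum3DDiameter"] == 0.0

    def test_digital_ball_sphericity(self):
        m = make_ball_mask((24, 24, 24), (11.5, 11.5, 11.5), 10.0)
        f = shape_features(m)
        assert 0.95 < f["Sphericity"] <= 1.0

    def test_spacing_scaling(self):
        m1 = make_ball_mask((16, 16, 16), (7.5, 7.5, 7.5), 5.0, spacing=(1, 1, 1))
        m2 = make_ball_mask((16, 16, 16), (7.5, 7.5, 7.5), 5.0, spacing=(2, 2, 2))
        f1, f2 = shape_features(m1), shape_features(m2)
        assert f2["VoxelVolume"] == pytest.approx(8 * f1["VoxelVolume"])
        assert f2["Maximum3DDiameter"] == pytest.approx(2 * f1["Maximum3DDiameter"])

    def test_elongated_mask_axes(self):
        data = np.zeros((20, 8, 8), dtype=np.uint8)
        data[2:18, 3:5, 3:5] = 1
        f = shape_features(MaskVolume(data=data))
        assert f["MajorAxisLength"] > f["MinorAxisLength"] >= f["LeastAxisLength"]
        assert f["Elongation"] < 0.5

    def test_all_names_emitted(self, rng):
        m = make_ball_mask((10, 10, 10), (4.5, 4.5, 4.5), 3.0)
        assert set(shape_features(m)) == set(SHAPE_NAMES)


class TestManifest:
    def test_default_inventory_counts(self):
        man = default_manifest()
        counts = man.category_counts()
        assert counts == {
            "shape": 14,
            "firstorder": 19,
            "texture": 172,
            "wavelet": 728,
            "log": 104,
        }
        assert len(man.entries) == 1037
        assert len(set(man.feature_names)) == 1037

    def test_sentinel_names_present(self):
        names = set(default_manifest().feature_names)
        assert "original_firstorder_Energy" in names
        assert "original_glrlm_GrayLevelNonUniformity" in names
        assert "wavelet-HLH_glrlm_GrayLevelNonUniformity" in names

    def test_duplicate_entries_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureManifest(
                entries=[("original", "firstorder", "Mean")] * 2
            )


class TestExtract:
    def test_original_features_invariant_to_outside_padding(self, rng):
        data = rng.normal(30, 20, size=(10, 10, 10))
        mask = np.zeros_like(data, dtype=np.uint8)
        mask[3:7, 3:7, 3:7] = 1
        man = FeatureManifest(
            entries=[("original", "firstorder", f) for f in FIRSTORDER_NAMES]
            + [("original", "glrlm", "GrayLevelNonUniformity")]
            + [("original", "glcm", "Contrast")]
            + [("original", "gldm", "DependenceEntropy")]
        )
        v = Volume(data=data)
        m = MaskVolume(data=mask)
        base = extract_features(v, m, man)
        padded_v = Volume(data=np.pad(data, 3, constant_values=500.0))
        padded_m = MaskVolume(data=np.pad(mask, 3))
        pad = extract_features(padded_v, padded_m, man)
        for k in base:
            assert base[k] == pytest.approx(pad[k], rel=1e-12), k

    def test_extraction_deterministic(self, rng):
        data = rng.normal(30, 20, size=(8, 8, 8))
        mask = np.zeros_like(data, dtype=np.uint8)
        mask[2:6, 2:6, 2:6] = 1
        man = FeatureManifest(
            entries=[("original", "firstorder", "Mean"),
                     ("wavelet-HLH", "glrlm", "GrayLevelNonUniformity"),
                     ("log-sigma-1mm", "glcm", "Contrast")]
        )
        v, m = Volume(data=data), MaskVolume(data=mask)
        assert extract_features(v, m, man) == extract_features(v, m, man)

    def test_empty_mask_rejected(self):
        v = Volume(data=np.zeros((4, 4, 4)))
        m = MaskVolume(data=np.zeros((4, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            extract_features(v, m, default_manifest())
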
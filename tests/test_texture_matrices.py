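"""Hand-computed worked examples for every texture-matrix class."""
import numpy as np
import pytest

from cbctomics.radiomics.discretize import DiscretizedROI
from cbctomics.radiomics.matrices import (
    glcm_features,
    glcm_matrix,
    gldm_features,
    glrlm_features,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
)


def roi(labels):
    labels = np.asarray(labels, dtype=np.int32)
    return DiscretizedROI(
        labels=labels,
        n_levels=int(labels.max()),
        bin_width=1.0,
        roi_min=0.0,
        spacing=(1.0, 1.0, 1.0),
    )


def line_roi(values):
    """1D ROI laid out along x in a (n, 1, 1) grid."""
    return roi(np.asarray(values, dtype=np.int32).reshape(-1, 1, 1))


class TestGLCM:
    def test_checkerboard_contrast(self):
        # 2x2 checkerboard, horizontal pairs (1,2) and (2,1):
        # symmetric P has all mass at |i-j| = 1 -> contrast = 1
        d = roi(np.array([[1, 2], [2, 1]], dtype=np.int32)[:, :, None])
        f = glcm_features(d, directions=[(1, 0, 0)])
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Correlation"] == pytest.approx(-1.0)

    def test_constant_roi_degenerate(self):
        d = roi(np.ones((3, 3, 1), dtype=np.int32))
        f = glcm_features(d)
        assert f["Contrast"] == 0.0
        assert f["Correlation"] == 1.0  # documented degenerate value
        assert f["JointEnergy"] == pytest.approx(1.0)

    def test_matrix_counts_single_direction(self):
        # [1,1,2] along x: ordered pairs (1,1), (1,2); symmetric counts
        d = line_roi([1, 1, 2])
        P = glcm_matrix(d, directions=[(1, 0, 0)])
        np.testing.assert_array_equal(P, [[2, 1], [1, 0]])

    def test_merged_directions_sum(self, rng):
        lab = rng.integers(1, 4, size=(4, 4, 4)).astype(np.int32)
        d = roi(lab)
        from cbctomics.radiomics.matrices import DIRECTIONS_13

        merged = glcm_matrix(d)
        summed = sum(glcm_matrix(d, directions=[dd]) for dd in DIRECTIONS_13)
        np.testing.assert_array_equal(merged, summed)


class TestGLRLM:
    def test_line_worked_example(self):
        # [1,1,2]: runs {(level 1, len 2), (level 2, len 1)}
        # GLNU = (1^2 + 1^2) / 2 = 1
        f = glrlm_features(line_roi([1, 1, 2]), directions=[(1, 0, 0)])
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)
        assert f["RunLengthNonUniformity"] == pytest.approx(1.0)
        # SRE = (1/4 + 1/1)/2 = 0.625 ; LRE = (4 + 1)/2 = 2.5
        assert f["ShortRunEmphasis"] == pytest.approx(0.625)
        assert f["LongRunEmphasis"] == pytest.approx(2.5)

    def test_constant_line_single_run(self):
        # constant ROI along a single line: one run, GLNU = 1
        f = glrlm_features(line_roi([1, 1, 1, 1]), directions=[(1, 0, 0)])
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)
        assert f["LongRunEmphasis"] == pytest.approx(16.0)
        assert f["RunPercentage"] == pytest.approx(1 / 4)

    def test_gray_level_permutation_leaves_glnu_unchanged(self, rng):
        lab = rng.integers(1, 5, size=(5, 5, 5)).astype(np.int32)
        d1 = roi(lab)
        perm = np.array([0, 3, 1, 4, 2])  # permutation of levels 1..4
        d2 = roi(perm[lab])
        f1 = glrlm_features(d1)
        f2 = glrlm_features(d2)
        assert f1["GrayLevelNonUniformity"] == pytest.approx(
            f2["GrayLevelNonUniformity"], rel=1e-12
        )


class TestGLSZM:
    def test_line_worked_example(self):
        # [1,1,2,1]: zones {level 1 size 2, level 1 size 1, level 2 size 1}
        d = line_roi([1, 1, 2, 1])
        S = glszm_matrix(d)
        np.testing.assert_array_equal(S, [[1, 1], [1, 0]])
        f = glszm_features(d)
        # SAE = (1/4 + 1 + 1)/3 ; GLN = (2^2 + 1^2)/3 ; ZP = 3/4
        assert f["SmallAreaEmphasis"] == pytest.approx((0.25 + 2) / 3)
        assert f["GrayLevelNonUniformity"] == pytest.approx(5 / 3)
        assert f["ZonePercentage"] == pytest.approx(0.75)

    def test_uniform_blob_single_zone(self):
        lab = np.zeros((5, 5, 5), dtype=np.int32)
        lab[1:4, 1:4, 1:4] = 1
        f = glszm_features(roi(lab))
        assert f["ZonePercentage"] == pytest.approx(1 / 27)
        assert f["LargeAreaEmphasis"] == pytest.approx(27.0**2)

    def test_diagonal_zones_merge_with_26_connectivity(self):
        lab = np.zeros((2, 2, 1), dtype=np.int32)
        lab[0, 0, 0] = 1
        lab[1, 1, 0] = 1
        S = glszm_matrix(roi(lab))
        assert S[0, 1] == 1  # one zone of size 2, not two of size 1


class TestGLDM:
    def test_line_worked_example(self):
        # [1,1,2], alpha=0: dependence sizes (centre counted):
        # voxel0 -> 2, voxel1 -> 2, voxel2 -> 1; D(1,2)=2, D(2,1)=1
        f = gldm_features(line_roi([1, 1, 2]))
        # SDE = (1/1 + 2/4)/3 = 0.5 ; LDE = (2*4 + 1)/3 = 3
        assert f["SmallDependenceEmphasis"] == pytest.approx(0.5)
        assert f["LargeDependenceEmphasis"] == pytest.approx(3.0)
        assert f["GrayLevelNonUniformity"] == pytest.approx(5 / 3)
        # p = {2/3, 1/3} over the two cells
        assert f["DependenceEntropy"] == pytest.approx(
            -(2 / 3) * np.log2(2 / 3) - (1 / 3) * np.log2(1 / 3)
        )

    def test_isolated_voxel_dependence_one(self):
        lab = np.zeros((3, 3, 3), dtype=np.int32)
        lab[1, 1, 1] = 1
        f = gldm_features(roi(lab))
        assert f["LargeDependenceEmphasis"] == pytest.approx(1.0)
        assert f["SmallDependenceEmphasis"] == pytest.approx(1.0)


class TestNGTDM:
    def test_line_worked_example(self):
        # [1,1,2]: neighbour means A = (1, 1.5, 1); s_1 = 0.5, s_2 = 1
        n, p, s = ngtdm_table(line_roi([1, 1, 2]))
        np.testing.assert_allclose(n, [2, 1])
        np.testing.assert_allclose(s, [0.5, 1.0])
        f = ngtdm_features(line_roi([1, 1, 2]))
        # Coarseness = 1/(2/3*0.5 + 1/3*1) = 1.5
        assert f["Coarseness"] == pytest.approx(1.5)
        # Contrast = [1/(2*1) * 2*(2/3)(1/3)*1] * [(0.5+1)/3] = 1/9
        assert f["Contrast"] == pytest.approx(1 / 9)

    def test_constant_roi(self):
        f = ngtdm_features(roi(np.ones((3, 3, 3), dtype=np.int32)))
        assert f["Contrast"] == 0.0
        assert f["Coarseness"] == pytest.approx(1e6)


class TestDegenerateSingleVoxel:
    def test_all_classes_return_finite_values(self):
        lab = np.zeros((3, 3, 3), dtype=np.int32)
        lab[1, 1, 1] = 1
        d = roi(lab)
        for fn in (glcm_features, glrlm_features, glszm_features, gldm_features,
                   ngtdm_features):
            vals = fn(d)
            assert all(np.isfinite(v) for v in vals.values()), fn.__name__
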
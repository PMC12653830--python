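import numpy as np
import pytest

from dceqc import texture
from dceqc.texture import (GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES,
                           NGTDM_NAMES, glcm_features, glcm_matrices,
                           gldm_features, gldm_matrix, glrlm_features,
                           glrlm_matrices, glszm_features, glszm_zones,
                           ngtdm_features, ngtdm_table)

from oracles import (brute_glcm, brute_gldm, brute_glrlm, brute_glszm,
                     brute_ngtdm)


def _random_case(rng, max_side=8, max_ng=4):
    h, w = rng.integers(2, max_side + 1, 2)
    levels = rng.integers(1, max_ng + 1, (h, w))
    mask = rng.random((h, w)) < 0.8
    if not mask.any():
        mask[0, 0] = True
    return levels, mask


class TestFeatureCounts:
    def test_class_counts(self, rng):
        lv = rng.integers(1, 5, (10, 10))
        mask = np.ones((10, 10), bool)
        assert len(glcm_features(lv, mask)) == 22
        assert len(gldm_features(lv, mask)) == 14
        assert len(glrlm_features(lv, mask)) == 16
        assert len(glszm_features(lv, mask)) == 16
        assert len(ngtdm_features(lv, mask)) == 5


class TestHandExamples:
    def test_checkerboard_direction_averaged_contrast(self):
        # horizontal and vertical neighbours always differ by 1 (contrast 1);
        # diagonal neighbours are always equal (contrast 0) -> mean 0.5
        lv = np.indices((4, 4)).sum(axis=0) % 2 + 1
        feats = glcm_features(lv, np.ones((4, 4), bool))
        assert feats["Contrast"] == pytest.approx(0.5)

    def test_run_example_1x4(self):
        # [1,1,2,2] horizontally: two runs of length 2
        lv = np.array([[1, 1, 2, 2]])
        m = glrlm_matrices(lv, np.ones((1, 4), bool))[0]  # horizontal
        assert m[0, 1] == 1 and m[1, 1] == 1 and m.sum() == 2
        # run-length non-uniformity: (2 runs of length 2)^2 / 2 runs = 2
        nr = m.sum()
        rln = (m.sum(axis=0) ** 2).sum() / nr
        assert rln == pytest.approx(2.0)

    def test_constant_region_degenerates(self):
        lv = np.ones((5, 5), dtype=int)
        mask = np.ones((5, 5), bool)
        g = glcm_features(lv, mask)
        assert g["Contrast"] == 0.0
        assert g["Correlation"] == 1.0  # defined by convention
        assert g["JointEntropy"] == 0.0
        z = glszm_features(lv, mask)
        assert z["ZoneEntropy"] == 0.0
        gv, sv, cv = glszm_zones(lv, mask)
        assert sv.tolist() == [25.0] and cv.tolist() == [1.0]  # one 25-px zone
        n = ngtdm_features(lv, mask)
        assert n["Complexity"] == 0.0 and n["Contrast"] == 0.0

    def test_coarseness_capped_on_uniform_region(self):
        feats = ngtdm_features(np.ones((4, 4), int), np.ones((4, 4), bool))
        assert feats["Coarseness"] == 1e6


class TestOracleEquivalence:
    """Vectorized matrices match naive pixel-loop enumeration exactly."""

    def test_glcm_matrices(self, rng):
        for _ in range(30):
            lv, mask = _random_case(rng)
            ng = int(np.where(mask, lv, 0).max())
            fast = glcm_matrices(lv, mask, ng)
            slow = brute_glcm(np.where(mask, lv, 0), mask, ng)
            for f, s in zip(fast, slow):
                np.testing.assert_array_equal(f, s)

    def test_glrlm_matrices(self, rng):
        for _ in range(30):
            lv, mask = _random_case(rng)
            ng = int(np.where(mask, lv, 0).max())
            lmax = max(lv.shape)
            fast = glrlm_matrices(lv, mask, ng)
            slow = brute_glrlm(np.where(mask, lv, 0), mask, ng, lmax)
            for f, s in zip(fast, slow):
                np.testing.assert_array_equal(f, s)

    def test_glszm_zones(self, rng):
        for _ in range(30):
            lv, mask = _random_case(rng)
            gv, sv, cv = glszm_zones(lv, mask)
            fast = {(int(g), int(s)): int(c) for g, s, c in zip(gv, sv, cv)}
            assert fast == brute_glszm(np.where(mask, lv, 0), mask)

    def test_gldm_matrix(self, rng):
        for _ in range(30):
            lv, mask = _random_case(rng)
            ng = int(np.where(mask, lv, 0).max())
            fast = gldm_matrix(lv, mask, alpha=0, ng=ng)
            np.testing.assert_array_equal(
                fast, brute_gldm(np.where(mask, lv, 0), mask, ng))

    def test_gldm_matrix_nonzero_alpha(self, rng):
        for _ in range(10):
            lv, mask = _random_case(rng)
            ng = int(np.where(mask, lv, 0).max())
            fast = gldm_matrix(lv, mask, alpha=1, ng=ng)
            np.testing.assert_array_equal(
                fast, brute_gldm(np.where(mask, lv, 0), mask, ng, alpha=1))

    def test_ngtdm_table(self, rng):
        for _ in range(30):
            lv, mask = _random_case(rng)
            gl, n_i, s_i = ngtdm_table(lv, mask)
            n_ref, s_ref = brute_ngtdm(np.where(mask, lv, 0), mask, len(gl))
            np.testing.assert_array_equal(n_i, n_ref)
            np.testing.assert_allclose(s_i, s_ref, atol=1e-10)


class TestProperties:
    def test_single_pixel_mask_is_finite(self):
        mask = np.zeros((6, 6), bool)
        mask[3, 3] = True
        lv = np.full((6, 6), 2, dtype=int)
        for fn in (glcm_features, gldm_features, glrlm_features,
                   glszm_features, ngtdm_features):
            feats = fn(lv, mask)
            assert all(np.isfinite(v) for v in feats.values()), fn.__name__

    def test_mask_gaps_break_runs(self):
        lv = np.array([[1, 1, 1, 1, 1]])
        mask = np.array([[True, True, False, True, True]])
        m = glrlm_matrices(lv, mask)[0]
        assert m[0, 1] == 2  # two runs of length 2, not one of length 5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            glcm_features(np.ones((3, 3), int), np.zeros((3, 3), bool))
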
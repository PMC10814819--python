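import numpy as np
import pytest
from scipy.ndimage import uniform_filter
from scipy.stats import binomtest

from berrylife import texture
from berrylife.imaging import ColorFeatures
from berrylife.texture import GrayROI, TextureConfig

from oracles import (
    glcm_bruteforce,
    glcm_features_bruteforce,
    rlm_features_bruteforce,
    runs_bruteforce,
)


class TestQuantize:
    @pytest.mark.parametrize("v,g,expected", [(0, 16, 0), (255, 16, 15), (128, 16, 8)])
    def test_uniform_binning(self, v, g, expected):
        q = texture.quantize(np.full((3, 3), v, float), g)
        assert np.all(q.pixels == expected)
        assert q.levels == g

    def test_levels_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            texture.quantize(np.zeros((2, 2)), 1)


class TestFirstOrder:
    def test_hand_computed_moments_and_energy(self):
        roi = GrayROI(np.array([[1, 1], [3, 3]]), levels=4)
        f = texture.first_order_features(roi)
        assert f == pytest.approx(
            {"mean": 2, "standard_deviation": 1, "skewness": 0, "kurtosis": 1, "energy": 0.5}
        )

    def test_constant_roi_degenerate_convention(self):
        f = texture.first_order_features(GrayROI(np.full((5, 5), 42.0)))
        assert f["mean"] == 42 and f["standard_deviation"] == 0
        assert f["skewness"] == 0 and f["kurtosis"] == 0
        assert f["energy"] == 1.0

    def test_energy_at_most_one(self, rng):
        for _ in range(20):
            roi = GrayROI(rng.integers(0, 256, (8, 8)).astype(float))
            e = texture.first_order_features(roi)["energy"]
            assert 0 < e <= 1


class TestGLCM:
    def test_diagonal_pairs(self):
        roi = GrayROI(np.array([[0, 0], [1, 1]]), levels=2)
        M = texture.compute_glcm(roi, offsets=[(0, 1)], symmetric=True)
        assert M.P == pytest.approx(np.array([[0.5, 0.0], [0.0, 0.5]]))

    def test_antidiagonal_pairs(self):
        roi = GrayROI(np.array([[0, 1], [0, 1]]), levels=2)
        M = texture.compute_glcm(roi, offsets=[(0, 1)], symmetric=True)
        assert M.P == pytest.approx(np.array([[0.0, 0.5], [0.5, 0.0]]))

    def test_constant_roi_single_cell(self):
        roi = texture.quantize(np.full((6, 6), 100.0), 16)
        M = texture.compute_glcm(roi)
        k = roi.pixels[0, 0]
        assert M.P[k, k] == 1.0

    def test_normalization_and_symmetry(self, rng):
        roi = texture.quantize(rng.integers(0, 256, (9, 9)).astype(float), 8)
        M = texture.compute_glcm(roi, symmetric=True)
        assert M.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(M.P, M.P.T)

    def test_offset_beyond_roi_raises(self):
        roi = GrayROI(np.array([[0, 1]]), levels=2)
        with pytest.raises(ValueError):
            texture.compute_glcm(roi, offsets=[(5, 0)])

    @pytest.mark.parametrize(
        "P,expected",
        [
            (
                np.array([[0.5, 0.0], [0.0, 0.5]]),
                dict(contrast=0, homogeneity=1, correlation=1,
                     dissimilarity=0, angular_second_moment=0.5),
            ),
            (
                np.array([[0.0, 0.5], [0.5, 0.0]]),
                dict(contrast=1, homogeneity=0.5, correlation=-1,
                     dissimilarity=1, angular_second_moment=0.5),
            ),
        ],
    )
    def test_feature_hand_values(self, P, expected):
        M = texture.GLCM(P, offsets=((0, 1),), symmetric=True)
        assert texture.glcm_features(M) == pytest.approx(expected)

    def test_degenerate_marginal_correlation_zero(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        f = texture.glcm_features(texture.GLCM(P, ((0, 1),), True))
        assert f["correlation"] == 0.0
        assert f["contrast"] == 0 and f["homogeneity"] == 1
        assert f["angular_second_moment"] == 1


class TestRLM:
    def test_single_row_runs(self):
        R = texture.compute_rlm(GrayROI(np.array([[1, 1, 1, 2, 2]]), levels=4), [0])
        assert R.n_runs == 2 and R.n_pixels == 5
        assert R.R[1, 2] == 1 and R.R[2, 1] == 1

    def test_constant_roi_one_run_per_row(self):
        R = texture.compute_rlm(GrayROI(np.zeros((4, 4), int), levels=2), [0])
        assert R.n_runs == 4
        f = texture.rlm_features(R)
        assert f == pytest.approx({"SRE": 0.0625, "LRE": 16, "GLN": 4, "RLN": 4, "RP": 0.25})

    def test_checkerboard_all_unit_runs(self):
        cb = np.indices((2, 2)).sum(axis=0) % 2
        R = texture.compute_rlm(GrayROI(cb, levels=2), [0])
        f = texture.rlm_features(R)
        assert f["SRE"] == 1 and f["LRE"] == 1 and f["RP"] == 1

    def test_two_runs_hand_values(self):
        R = texture.compute_rlm(GrayROI(np.array([[1, 1, 1, 2, 2]]), levels=4), [0])
        f = texture.rlm_features(R)
        assert f["SRE"] == pytest.approx((1 / 9 + 1 / 4) / 2)
        assert f["LRE"] == pytest.approx(6.5)
        assert f["GLN"] == 1 and f["RLN"] == 1 and f["RP"] == pytest.approx(0.4)

    def test_pixel_count_identity_per_direction(self, rng):
        for _ in range(10):
            roi = texture.quantize(rng.integers(0, 256, (7, 9)).astype(float), 4)
            for d in (0, 90):
                R = texture.compute_rlm(roi, [d])
                lengths = np.arange(1, R.R.shape[1] + 1)
                assert np.sum(R.R * lengths) == roi.pixels.size

    def test_sre_lre_bracket_one(self, rng):
        for _ in range(10):
            roi = texture.quantize(rng.integers(0, 256, (8, 8)).astype(float), 4)
            f = texture.rlm_features(texture.compute_rlm(roi))
            assert f["SRE"] <= 1 + 1e-12 <= f["LRE"] + 2e-12


class TestOracleEquivalence:
    """GLCM and run-length paths against naive enumeration, 1e-9."""

    def test_glcm_matches_bruteforce(self, rng):
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
        for k in range(100):
            g = 4 if k % 2 == 0 else 8
            roi = texture.quantize(rng.integers(0, 256, (8, 8)).astype(float), g)
            M = texture.compute_glcm(roi, offsets=offsets, symmetric=True)
            P_ref = glcm_bruteforce(roi.pixels, g, offsets, symmetric=True)
            np.testing.assert_allclose(M.P, P_ref, atol=1e-9)
            f = texture.glcm_features(M)
            f_ref = glcm_features_bruteforce(P_ref)
            for name in f:
                assert f[name] == pytest.approx(f_ref[name], abs=1e-9)

    def test_rlm_matches_bruteforce(self, rng):
        for k in range(100):
            g = 4 if k % 2 == 0 else 8
            roi = texture.quantize(rng.integers(0, 256, (8, 8)).astype(float), g)
            R = texture.compute_rlm(roi, [0, 90])
            runs = runs_bruteforce(roi.pixels, [0, 90])
            assert R.n_runs == len(runs)
            f = texture.rlm_features(R)
            f_ref = rlm_features_bruteforce(runs, roi.pixels.size * 2)
            for name in f:
                assert f[name] == pytest.approx(f_ref[name], abs=1e-9)


class TestBlurMonotonicity:
    def test_smoothing_decreases_contrast_increases_homogeneity(self, rng):
        """Blurring noise must lower GLCM contrast and raise homogeneity."""
        wins = 0
        n = 30
        for _ in range(n):
            noise = rng.uniform(0, 255, (32, 32))
            sharp = texture.quantize(np.clip(noise, 0, 255), 16)
            blurred = texture.quantize(np.clip(uniform_filter(noise, 3), 0, 255), 16)
            fs = texture.glcm_features(texture.compute_glcm(sharp))
            fb = texture.glcm_features(texture.compute_glcm(blurred))
            if fb["contrast"] < fs["contrast"] and fb["homogeneity"] > fs["homogeneity"]:
                wins += 1
        assert binomtest(wins, n, 0.5, alternative="greater").pvalue < 0.01


class TestFeatureVector:
    def test_degenerate_composition(self):
        fv = texture.feature_vector(
            np.full((15, 15), 200.0), ColorFeatures(100.0, 0.0, 0.0)
        )
        assert fv["contrast"] == 0 and fv["angular_second_moment"] == 1
        assert fv["energy"] == 1 and fv["L_star"] == 100

    def test_schema_18_canonical_names(self, rng):
        fv = texture.feature_vector(
            rng.uniform(0, 255, (15, 15)), ColorFeatures(50.0, 10.0, 5.0)
        )
        assert list(fv) == texture.FEATURE_NAMES
        assert len(fv) == 18

    def test_deterministic_given_same_input(self, rng):
        roi = rng.uniform(0, 255, (15, 15))
        c = ColorFeatures(40.0, 20.0, 10.0)
        assert texture.feature_vector(roi, c) == texture.feature_vector(roi.copy(), c)
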
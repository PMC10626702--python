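import math
import warnings

import numpy as np
import pytest

from radtex.texture_glcm import (
    GLCM,
    GLCM_FEATURE_NAMES,
    GLCMParams,
    compute_glcm,
    glcm_contrast,
    glcm_correlation,
    glcm_energy,
    glcm_feature_vector,
    glcm_homogeneity,
    quantize,
)

ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(patch, angles, d=1, G=8, symmetric=True):
    """Brute-force pair enumeration over every pixel and angle."""
    patch = np.asarray(patch, dtype=int)
    h, w = patch.shape
    counts = np.zeros((G, G), dtype=float)
    for angle in angles:
        dr, dc = ANGLE_STEPS[angle]
        dr, dc = dr * d, dc * d
        for r in range(h):
            for c in range(w):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    counts[patch[r, c], patch[rr, cc]] += 1
                    if symmetric:
                        counts[patch[rr, cc], patch[r, c]] += 1
    return counts / counts.sum()


def feature_oracle(P):
    """Independent recomputation of all 13 features from the enumerated
    pair distribution, using scalar loops and math functions only."""
    G = P.shape[0]
    px = [sum(P[i][j] for j in range(G)) for i in range(G)]
    py = [sum(P[i][j] for i in range(G)) for j in range(G)]
    mux = sum(i * px[i] for i in range(G))
    muy = sum(j * py[j] for j in range(G))
    sx = math.sqrt(sum((i - mux) ** 2 * px[i] for i in range(G)))
    sy = math.sqrt(sum((j - muy) ** 2 * py[j] for j in range(G)))

    def total(fn):
        return sum(fn(i, j, P[i][j]) for i in range(G) for j in range(G))

    if sx > 0 and sy > 0:
        corr = (total(lambda i, j, p: i * j * p) - mux * muy) / (sx * sy)
    else:
        corr = 0.0
    hxy = -total(lambda i, j, p: p * math.log(p) if p > 0 else 0.0)
    hxy1 = -total(lambda i, j, p: p * math.log(px[i] * py[j]) if p > 0 else 0.0)
    hx = -sum(p * math.log(p) for p in px if p > 0)
    hy = -sum(p * math.log(p) for p in py if p > 0)
    denom = max(hx, hy)
    return {
        "autocorrelation": total(lambda i, j, p: i * j * p),
        "contrast": total(lambda i, j, p: (i - j) ** 2 * p),
        "correlation": corr,
        "cluster_prominence": total(lambda i, j, p: (i + j - mux - muy) ** 4 * p),
        "cluster_shade": total(lambda i, j, p: (i + j - mux - muy) ** 3 * p),
        "energy": total(lambda i, j, p: p * p),
        "dissimilarity": total(lambda i, j, p: abs(i - j) * p),
        "homogeneity": total(lambda i, j, p: p / (1 + abs(i - j))),
        "info_measure_corr_1": 0.0 if denom == 0 else (hxy - hxy1) / denom,
        "maximum_probability": max(max(row) for row in P),
        "inverse_difference": total(lambda i, j, p: p / (1 + (i - j) ** 2)),
        "inverse_difference_normalized": total(lambda i, j, p: p / (1 + abs(i - j) / G)),
        "inverse_difference_moment_normalized": total(
            lambda i, j, p: p / (1 + (i - j) ** 2 / G**2)
        ),
    }


class TestQuantize:
    @pytest.mark.parametrize("pixel,expected", [(0, 0), (255, 7), (128, 4), (31, 0), (32, 1)])
    def test_uniform_binning(self, pixel, expected):
        assert quantize(np.array([[pixel]]), 8)[0, 0] == expected

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2)), 1)


class TestComputeGLCM:
    def test_constant_patch_single_entry(self):
        q = np.full((5, 5), 3)
        glcm = compute_glcm(q)
        assert glcm.P[3, 3] == 1.0
        assert glcm.P.sum() == pytest.approx(1.0)

    def test_two_by_two_hand_count(self):
        q = np.array([[0, 1], [0, 1]])
        params = GLCMParams(distance=1, angles=(0,), gray_levels=2, symmetric=True)
        glcm = compute_glcm(q, params)
        np.testing.assert_allclose(glcm.P, [[0, 0.5], [0.5, 0]])

    @pytest.mark.parametrize("symmetric", [True, False])
    @pytest.mark.parametrize("angles", [(0,), (90,), (45, 135), (0, 45, 90, 135)])
    def test_matches_bruteforce_oracle(self, angles, symmetric):
        rng = np.random.default_rng(3)
        for _ in range(5):
            q = rng.integers(0, 8, (6, 6))
            params = GLCMParams(angles=angles, symmetric=symmetric)
            expected = glcm_oracle(q, angles, symmetric=symmetric)
            np.testing.assert_allclose(compute_glcm(q, params).P, expected, atol=1e-12)

    def test_normalization_and_symmetry(self, rng):
        for _ in range(10):
            q = rng.integers(0, 8, (8, 8))
            glcm = compute_glcm(q)
            assert glcm.P.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(glcm.P, glcm.P.T, atol=1e-12)

    def test_no_valid_pairs_rejected(self):
        with pytest.raises(ValueError, match="no valid"):
            compute_glcm(np.array([[1]]), GLCMParams(angles=(0,)))

    def test_unquantized_patch_rejected(self):
        with pytest.raises(ValueError, match="quantized"):
            compute_glcm(np.array([[0, 200], [1, 2]]))


class TestScalarFeatures:
    ANTIDIAG = GLCM(P=np.array([[0.0, 0.5], [0.5, 0.0]]))

    def test_constant_image_energy_is_one(self):
        glcm = compute_glcm(np.full((6, 6), 2))
        assert glcm_energy(glcm) == pytest.approx(1.0)
        assert glcm_contrast(glcm) == pytest.approx(0.0)
        assert glcm_homogeneity(glcm) == pytest.approx(1.0)

    def test_uniform_matrix_energy(self):
        g = 4
        glcm = GLCM(P=np.full((g, g), 1 / g**2))
        assert glcm_energy(glcm) == pytest.approx(1 / g**2)

    def test_antidiagonal_two_level_case(self):
        assert glcm_energy(self.ANTIDIAG) == pytest.approx(0.5)
        assert glcm_contrast(self.ANTIDIAG) == pytest.approx(1.0)
        assert glcm_correlation(self.ANTIDIAG) == pytest.approx(-1.0)
        assert glcm_homogeneity(self.ANTIDIAG) == pytest.approx(0.5)

    def test_perfect_diagonal_correlation(self):
        glcm = GLCM(P=np.diag([0.5, 0.5]))
        assert glcm_correlation(glcm) == pytest.approx(1.0)

    def test_uniform_two_level_homogeneity(self):
        glcm = GLCM(P=np.full((2, 2), 0.25))
        assert glcm_homogeneity(glcm) == pytest.approx(0.75)

    def test_degenerate_correlation_warns_zero(self):
        glcm = compute_glcm(np.full((4, 4), 1))
        with pytest.warns(UserWarning, match="degenerate"):
            assert glcm_correlation(glcm) == 0.0

    def test_correlation_matches_pearson_oracle(self, rng):
        for _ in range(10):
            q = rng.integers(0, 8, (8, 8))
            glcm = compute_glcm(q)
            # Pearson correlation of the (i, j) pair distribution
            g = glcm.P.shape[0]
            i, j = np.indices((g, g))
            w = glcm.P.ravel()
            iv, jv = i.ravel().astype(float), j.ravel().astype(float)
            mi, mj = (w * iv).sum(), (w * jv).sum()
            cov = (w * (iv - mi) * (jv - mj)).sum()
            denom = np.sqrt((w * (iv - mi) ** 2).sum() * (w * (jv - mj) ** 2).sum())
            assert glcm_correlation(glcm) == pytest.approx(cov / denom, abs=1e-10)

    def test_contrast_identity(self, rng):
        # sum_n n^2 sum_{|i-j|=n} P == sum (i-j)^2 P
        q = rng.integers(0, 8, (8, 8))
        glcm = compute_glcm(q)
        g = glcm.P.shape[0]
        by_n = sum(
            n**2 * glcm.P[np.abs(np.subtract.outer(range(g), range(g))) == n].sum()
            for n in range(g)
        )
        assert glcm_contrast(glcm) == pytest.approx(by_n, abs=1e-12)


class TestFeatureVector:
    def test_returns_13_features_in_order(self, random_patch):
        feats = glcm_feature_vector(random_patch)
        assert tuple(feats) == GLCM_FEATURE_NAMES
        assert len(feats) == 13

    def test_constant_patch_values(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = glcm_feature_vector(np.full((40, 40), 100, dtype=np.uint8))
        assert feats["energy"] == pytest.approx(1.0)
        assert feats["contrast"] == pytest.approx(0.0)
        assert feats["homogeneity"] == pytest.approx(1.0)
        assert feats["dissimilarity"] == pytest.approx(0.0)
        assert feats["maximum_probability"] == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            patch = rng.integers(0, 256, (6, 6), dtype=np.uint8)
            q = quantize(patch, 8)
            expected = {name: 0.0 for name in GLCM_FEATURE_NAMES}
            for angle in (0, 45, 90, 135):
                oracle = feature_oracle(glcm_oracle(q, (angle,)))
                for name in expected:
                    expected[name] += oracle[name] / 4
            feats = glcm_feature_vector(patch)
            for name in GLCM_FEATURE_NAMES:
                assert feats[name] == pytest.approx(expected[name], abs=1e-10), name

    def test_rotation_invariance_of_angle_average(self, rng):
        for _ in range(5):
            patch = rng.integers(0, 256, (10, 12), dtype=np.uint8)
            a = glcm_feature_vector(patch)
            b = glcm_feature_vector(np.rot90(patch))
            for name in GLCM_FEATURE_NAMES:
                assert a[name] == pytest.approx(b[name], abs=1e-10), name

    def test_feature_ranges(self, rng):
        for _ in range(10):
            patch = rng.integers(0, 256, (12, 12), dtype=np.uint8)
            feats = glcm_feature_vector(patch)
            assert 0 < feats["energy"] <= 1
            assert 0 < feats["homogeneity"] <= 1
            assert -1 <= feats["correlation"] <= 1
            assert feats["contrast"] >= 0
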
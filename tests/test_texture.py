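"""Masked GLCM construction and Haralick-type feature formulas."""

import math

import numpy as np
import pytest

from radgs.features import FEATURE_NAMES
from radgs.roi import ROIMask
from radgs.texture import (
    DIRECTIONS,
    GLCM,
    QuantizationSpec,
    extract_features,
    glcm,
    glcm_features,
    quantize,
)
from tests.conftest import make_map


def brute_glcm(levelimg, mask, offset, levels):
    """Double-loop pair counting oracle (symmetric, normalized)."""
    dr, dc = offset
    h, w = levelimg.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = levelimg[r, c] - 1, levelimg[r2, c2] - 1
                counts[i, j] += 1
                counts[j, i] += 1
    s = counts.sum()
    return counts / s if s else counts


def brute_features(p):
    """Naive double-sum evaluation of the six feature formulas."""
    n = p.shape[0]
    energy = entropy = contrast = homog = idm = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            mu_i += (i + 1) * p[i, j]
            mu_j += (j + 1) * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(n):
        for j in range(n):
            pij = p[i, j]
            energy += pij**2
            if pij > 0:
                entropy -= pij * math.log(pij)
            contrast += (i - j) ** 2 * pij
            homog += pij / (1 + abs(i - j))
            idm += pij / (1 + (i - j) ** 2)
            var_i += (i + 1 - mu_i) ** 2 * pij
            var_j += (j + 1 - mu_j) ** 2 * pij
            cov += (i + 1 - mu_i) * (j + 1 - mu_j) * pij
    corr = cov / math.sqrt(var_i * var_j) if var_i * var_j > 0 else 0.0
    return dict(
        energy=energy, entropy=entropy, contrast=contrast,
        correlation=corr, homogeneity=homog, IDM=idm,
    )


def checkerboard(n=4):
    return np.indices((n, n)).sum(axis=0) % 2  # 0/1 pattern


class TestQuantize:
    def test_two_point_range(self):
        g = np.array([[0.0, 1.0]])
        out = quantize(g, np.ones((1, 2), bool), QuantizationSpec(levels=2))
        assert out.tolist() == [[1, 2]]

    def test_constant_roi_is_level_one(self):
        out = quantize(np.full((3, 3), 5.0), np.ones((3, 3), bool), QuantizationSpec())
        assert np.all(out == 1)

    def test_matches_floor_formula_oracle(self, rng):
        g = rng.random((40, 25)) * 10
        spec = QuantizationSpec(levels=16)
        mask = np.ones(g.shape, bool)
        out = quantize(g, mask, spec)
        lo, hi = g.min(), g.max()
        for r in range(g.shape[0]):
            for c in range(g.shape[1]):
                expect = 1 + math.floor((g[r, c] - lo) / (hi - lo) * 16)
                assert out[r, c] == min(max(expect, 1), 16)


class TestGLCM:
    def test_constant_roi_single_cell(self):
        lv = np.ones((2, 2), dtype=int)
        g = glcm(lv, np.ones((2, 2), bool), (0, 1), levels=4)
        assert g.counts.sum() == pytest.approx(1.0)
        assert g.counts[0, 0] == pytest.approx(1.0)

    def test_checkerboard_mass_split(self):
        lv = checkerboard() + 1
        g = glcm(lv, np.ones((4, 4), bool), (0, 1), levels=2)
        assert g.counts[0, 1] == pytest.approx(0.5)
        assert g.counts[1, 0] == pytest.approx(0.5)

    def test_no_pairs_direction_flagged(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[2, 2] = True  # no unit-offset pair exists
        g = glcm(np.ones((3, 3), dtype=int), mask, (0, 1), levels=2)
        assert g.n_pairs == 0 and not g.normalized
        assert np.all(g.counts == 0)

    @pytest.mark.parametrize("offset", DIRECTIONS)
    def test_matches_brute_force_oracle(self, offset, rng):
        for _ in range(25):
            lv = rng.integers(1, 7, size=(8, 8))
            mask = rng.random((8, 8)) < 0.6
            got = glcm(lv, mask, offset, levels=6)
            expect = brute_glcm(lv, mask, offset, 6)
            assert np.array_equal(got.counts, expect) or np.allclose(got.counts, expect, atol=1e-15)

    def test_matches_skimage_on_full_rectangle(self, rng):
        """Cross-check against an independent library implementation on a
        rectangular (unmasked) image, where both definitions coincide."""
        from skimage.feature import graycomatrix

        img = rng.integers(0, 5, size=(12, 12)).astype(np.uint8)
        ours = glcm(img + 1, np.ones(img.shape, bool), (0, 1), levels=5)
        ref = graycomatrix(img, [1], [0], levels=5, symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(ours.counts, ref, atol=1e-12)


class TestGLCMFeatures:
    def test_single_cell_diagonal(self):
        counts = np.zeros((4, 4))
        counts[1, 1] = 1.0
        f = glcm_features(GLCM(counts, (0, 1), True, 1))
        assert f == {
            "energy": 1.0, "entropy": 0.0, "contrast": 0.0,
            "correlation": 0.0, "homogeneity": 1.0, "IDM": 1.0,
        }

    def test_checkerboard_hand_values(self):
        lv = checkerboard() + 1
        f = glcm_features(glcm(lv, np.ones((4, 4), bool), (0, 1), levels=2))
        assert f["energy"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(math.log(2))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)
        assert f["homogeneity"] == pytest.approx(0.5)
        assert f["IDM"] == pytest.approx(0.5)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(GLCM(np.ones((2, 2)), (0, 1), False, 0))

    def test_matches_double_sum_oracle_and_bounds(self, rng):
        for _ in range(100):
            raw = rng.random((6, 6))
            p = (raw + raw.T) / (2 * raw.sum())  # symmetric, normalized
            got = glcm_features(GLCM(p, (0, 1), True, 1))
            expect = brute_features(p)
            for k in got:
                assert got[k] == pytest.approx(expect[k], abs=1e-12)
            assert 0 < got["energy"] <= 1
            assert 0 < got["homogeneity"] <= 1 and 0 < got["IDM"] <= 1
            assert -1 <= got["correlation"] <= 1
            assert 0 <= got["entropy"] <= math.log(36)


class TestExtractFeatures:
    @staticmethod
    def maps_from(grids):
        return {
            "ADC": make_map(grids["ADC"], "ADC"),
            "ALPHA": make_map(grids["ALPHA"], "ALPHA"),
            "T2": make_map(grids["T2"], "T2"),
        }

    def test_constant_maps(self):
        mask = ROIMask(np.ones((6, 6), bool))
        maps = self.maps_from({"ADC": np.full((6, 6), 1.3), "ALPHA": np.full((6, 6), 0.4), "T2": np.full((6, 6), 90.0)})
        f = extract_features(maps, mask)
        assert f["ADC"] == pytest.approx(1.3)
        assert f["ALPHE"] == pytest.approx(0.4)
        assert f["T2"] == pytest.approx(90.0)
        for prefix in ("ADC", "DCE", "T2"):
            assert f[f"{prefix}-energy"] == pytest.approx(1.0)
            assert f[f"{prefix}-entropy"] == pytest.approx(0.0)

    def test_always_21_named_entries(self, rng):
        mask = ROIMask(rng.random((10, 10)) < 0.5)
        if mask.area < 4:
            mask = ROIMask(np.ones((10, 10), bool))
        maps = self.maps_from({k: rng.random((10, 10)) + 0.5 for k in ("ADC", "ALPHA", "T2")})
        f = extract_features(maps, mask)
        assert set(f) == set(FEATURE_NAMES)

    def test_transpose_averages_invariant(self, rng):
        """Transposition permutes 0/90 and 45/135 directions, leaving the
        4-direction average unchanged."""
        g = rng.random((12, 12)) + 1.0
        mask = np.ones((12, 12), bool)
        spec = QuantizationSpec(levels=8)
        def avg_features(grid):
            lv = quantize(grid, mask, spec)
            per = [glcm_features(glcm(lv, mask, off, 8)) for off in DIRECTIONS]
            return {k: np.mean([d[k] for d in per]) for k in per[0]}
        a = avg_features(g)
        b = avg_features(g.T)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_isotropic_field_direction_spread_small(self):
        """On an isotropic smooth field the per-direction features agree to
        a coefficient of variation < 0.2 on average over seeds."""
        from scipy.ndimage import gaussian_filter

        spec = QuantizationSpec()
        mask = np.ones((20, 20), bool)
        cvs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            g = gaussian_filter(r.standard_normal((20, 20)), 1.5)
            lv = quantize(g, mask, spec)
            per = [glcm_features(glcm(lv, mask, off, spec.levels)) for off in DIRECTIONS]
            for k in ("entropy", "contrast", "homogeneity"):
                vals = np.array([d[k] for d in per])
                cvs.append(vals.std() / abs(vals.mean()))
        assert np.mean(cvs) < 0.2
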
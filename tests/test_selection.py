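"""ReliefF weights, the weight>0 retention rule, ANOVA screen, t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radgs import reference
from radgs.selection import (
    WeightVector,
    anova_screen,
    relieff,
    select_positive,
    ttest_summary,
)


def naive_relieff(x, y, k):
    """Literal loop-by-loop ReliefF (range-normalized, Manhattan distance,
    prior-weighted misses, ties by lowest index)."""
    n, nf = x.shape
    lo, hi = x.min(0), x.max(0)
    rng_ = np.where(hi - lo > 0, hi - lo, 1.0)
    xn = np.where(hi - lo > 0, (x - lo) / rng_, 0.0)
    classes, counts = np.unique(y, return_counts=True)
    prior = dict(zip(classes, counts / n))
    w = np.zeros(nf)
    for i in range(n):
        d = np.abs(xn - xn[i]).sum(1)
        for c in classes:
            pool = [j for j in range(n) if y[j] == c and j != i]
            pool.sort(key=lambda j: (d[j], j))
            kk = min(k, len(pool))
            near = pool[:kk]
            contrib = sum(np.abs(xn[j] - xn[i]) for j in near) / kk
            if c == y[i]:
                w -= contrib / n
            else:
                w += prior[c] / (1 - prior[y[i]]) * contrib / n
    return w


class TestReliefF:
    def test_label_copy_feature_wins(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1], 20)
            x = np.column_stack([y.astype(float)] + [r.standard_normal(40) for _ in range(4)])
            w = relieff(x, y, k=5)
            weights = np.array(list(w.weights.values()))
            assert np.argmax(weights) == 0
            assert weights[0] > 0

    def test_constant_feature_weight_zero(self, rng):
        x = np.column_stack([np.full(30, 3.7), rng.standard_normal(30)])
        y = np.repeat([0, 1], 15)
        assert relieff(x, y, k=3).weights["f0"] == 0.0

    def test_matches_hand_unrolled_iteration(self, rng):
        x = rng.random((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        w = relieff(x, y, k=1)
        expect = naive_relieff(x, y, 1)
        assert np.allclose(list(w.weights.values()), expect, atol=1e-12)

    def test_deterministic(self, rng):
        x = rng.random((25, 5))
        y = rng.integers(0, 2, 25)
        while len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
            y = rng.integers(0, 2, 25)
        assert relieff(x, y, k=3).weights == relieff(x, y, k=3).weights

    def test_permutation_drives_weights_to_zero(self):
        r = np.random.default_rng(7)
        x = r.standard_normal((50, 5))
        means = []
        for _ in range(100):
            y = r.permutation(np.repeat([0, 1], 25))
            w = relieff(x, y, k=10)
            means.append(np.mean(list(w.weights.values())))
        assert abs(np.mean(means)) < 0.05

    def test_weight_monotone_in_class_separation(self):
        """Growing one feature's between-class gap never lowers its weight."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            noise = r.standard_normal((40, 3))
            y = np.repeat([0, 1], 20)
            prev = -np.inf
            for gap in (0.0, 1.0, 2.0):
                x = noise.copy()
                x[:, 0] = r.standard_normal(40) * 0.5 + gap * y
                w = relieff(x, y, k=5).weights["f0"]
                assert w >= prev - 1e-9
                prev = w

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            relieff(np.random.default_rng(0).random((5, 2)), np.array([0, 0, 0, 0, 1]), k=1)


class TestSelectPositive:
    def test_reference_significant_column_keeps_13(self):
        sel = select_positive(WeightVector(reference.RELIEFF_WEIGHTS_SIGNIFICANT, 10, 50))
        assert len(sel.kept) == 13
        assert set(sel.kept) == {
            "ADC", "ALPHE", "T2", "ADC-contrast", "ADC-homogeneity",
            "DCE-correlation", "DCE-energy", "DCE-entropy", "DCE-homogeneity",
            "T2-IDM", "T2-energy", "T2-entropy", "T2-homogeneity",
        }
        assert sel.kept[0] == "ALPHE"  # largest weight first

    def test_reference_grade_column_keeps_8(self):
        sel = select_positive(WeightVector(reference.RELIEFF_WEIGHTS_GRADE, 10, 37))
        assert len(sel.kept) == 8
        assert set(sel.kept) == {
            "T2", "ADC-contrast", "ADC-correlation", "ADC-entropy",
            "ADC-homogeneity", "DCE-correlation", "DCE-energy", "DCE-homogeneity",
        }
        assert sel.kept[0] == "ADC-correlation"

    def test_all_negative_is_error(self):
        with pytest.raises(ValueError, match="threshold"):
            select_positive(WeightVector({"a": -0.1, "b": 0.0}, 10, 5))

    def test_kept_sound_discarded_sound(self, rng):
        weights = {f"f{i}": float(v) for i, v in enumerate(rng.normal(0, 0.05, 21))}
        if all(v <= 0 for v in weights.values()):
            weights["f0"] = 0.01
        sel = select_positive(WeightVector(weights, 10, 50))
        assert all(weights[f] > 0 for f in sel.kept)
        assert all(weights[f] <= 0 for f in set(weights) - set(sel.kept))


class TestAnovaScreen:
    def test_f_statistic_matches_hand_computation(self):
        # 3 groups x 4 samples, one feature; textbook between/within ratio
        g = [np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 3.0, 4.0, 5.0]), np.array([6.0, 7.0, 8.0, 9.0])]
        table = pd.DataFrame({"feat": np.concatenate(g)})
        labels = np.repeat([0, 1, 2], 4)
        res = anova_screen(table, labels)
        grand = np.concatenate(g).mean()
        ss_between = sum(4 * (x.mean() - grand) ** 2 for x in g)
        ss_within = sum(((x - x.mean()) ** 2).sum() for x in g)
        f_hand = (ss_between / 2) / (ss_within / 9)
        assert res.loc["feat", "F"] == pytest.approx(f_hand)
        assert res.loc["feat", "p"] == pytest.approx(1 - stats.f.cdf(f_hand, 2, 9))

    def test_gross_separation(self, rng):
        table = pd.DataFrame({"x": np.concatenate([rng.normal(m, 0.1, 10) for m in (0, 0, 5)])})
        labels = np.repeat([0, 1, 2], 10)
        assert anova_screen(table, labels).loc["x", "p"] < 1e-6

    def test_degenerate_variance_convention(self):
        table = pd.DataFrame({
            "sep": np.repeat([0.0, 1.0, 2.0], 3),
            "flat": np.zeros(9),
        })
        labels = np.repeat([0, 1, 2], 3)
        res = anova_screen(table, labels)
        assert res.loc["sep", "p"] == 0.0
        assert res.loc["flat", "p"] == 1.0


class TestTTestSummary:
    def test_identical_groups_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = pd.DataFrame({"x": np.concatenate([x, x])})
        res = ttest_summary(table, np.repeat([0, 1], 5))
        assert res.loc["x", "p"] == pytest.approx(1.0)
        assert res.loc["x", "mean1"] == res.loc["x", "mean2"]

    def test_gross_separation(self, rng):
        table = pd.DataFrame({"x": np.concatenate([rng.normal(0, 0.1, 20), rng.normal(1, 0.1, 20)])})
        assert ttest_summary(table, np.repeat([0, 1], 20)).loc["x", "p"] < 1e-10

    def test_welch_statistic_matches_hand_formula(self):
        a = np.array([4.1, 5.2, 6.3, 5.5, 4.9])
        b = np.array([6.8, 7.1, 5.9, 7.4, 6.6])
        table = pd.DataFrame({"x": np.concatenate([a, b])})
        res = ttest_summary(table, np.repeat([0, 1], 5))
        se = np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
        assert res.loc["x", "t"] == pytest.approx((a.mean() - b.mean()) / se)
        assert res.loc["x", "sd1"] == pytest.approx(a.std(ddof=1))
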
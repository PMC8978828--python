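import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from selenergy import GroupLabels, LogratioFrame, dcv_component_matrix, dcv_scores
from selenergy.dcv import DCVMatrix


def frame(values, n_ratios=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] == 1 and n_ratios is None:
        ratios = [("a", "b")]
    else:
        ratios = [(f"n{i}", f"d{i}") for i in range(values.shape[1])]
    return LogratioFrame(values, ratios)


def labels(n1, n2):
    return GroupLabels(np.array(["g1"] * n1 + ["g2"] * n2))


# -- independent oracles ------------------------------------------------------

def ks_bruteforce(x1, x2):
    """Sup over all thresholds of |ecdf1 - ecdf2| (weak inequality ecdf)."""
    best = 0.0
    for t in np.concatenate([x1, x2]):
        f1 = np.mean(x1 <= t)
        f2 = np.mean(x2 <= t)
        best = max(best, abs(f1 - f2))
    return best


def entropy(y):
    h = 0.0
    n = len(y)
    for c in set(y):
        p = sum(1 for v in y if v == c) / n
        h -= p * math.log(p)
    return h


def mdl_info_gain_reference(x, y):
    """Straightforward recursive Fayyad-Irani MDL partition (natural log)."""
    order = np.argsort(x, kind="stable")
    xs, ys = np.asarray(x)[order], np.asarray(y)[order]
    cuts = []

    def recurse(lo, hi):
        seg_x, seg_y = xs[lo:hi], ys[lo:hi]
        m = hi - lo
        h_s = entropy(seg_y)
        if m < 2 or h_s == 0:
            return
        best = None
        for i in range(m - 1):
            if seg_x[i] < seg_x[i + 1]:
                left, right = seg_y[:i + 1], seg_y[i + 1:]
                we = (len(left) * entropy(left) + len(right) * entropy(right)) / m
                if best is None or we < best[0]:
                    best = (we, i, left, right)
        if best is None:
            return
        we, i, left, right = best
        gain = h_s - we
        k1 = len(set(left))
        k2 = len(set(right))
        delta = math.log(3 ** 2 - 2) - (2 * h_s - k1 * entropy(left)
                                        - k2 * entropy(right))
        if gain > (math.log(m - 1) + delta) / m:
            cuts.append(lo + i)
            recurse(lo, lo + i + 1)
            recurse(lo + i + 1, hi)

    recurse(0, len(xs))
    if not cuts:
        if xs[0] == xs[-1] or entropy(ys) == 0:
            return 0.0
        med = 0.5 * (xs[(len(xs) - 1) // 2] + xs[len(xs) // 2])
        nl = int(np.sum(xs < med)) or int(np.sum(xs <= med))
        if nl == 0 or nl == len(xs):
            return 0.0
        bounds = [0, nl, len(xs)]
    else:
        bounds = [0] + sorted(c + 1 for c in cuts) + [len(xs)]
    cond = sum((b - a) * entropy(ys[a:b]) for a, b in zip(bounds, bounds[1:]))
    return entropy(ys) - cond / len(xs)


# -- component tests ----------------------------------------------------------

class TestComponents:
    def test_constant_logratio_all_zero(self):
        Z = frame(np.full((8, 1), 3.7))
        V = dcv_component_matrix(Z, labels(4, 4))
        np.testing.assert_array_equal(V.components, 0.0)

    def test_welch_hand_value(self):
        Z = frame([[0.0], [2.0], [3.0], [5.0]])
        V = dcv_component_matrix(Z, labels(2, 2))
        assert V.components[0, 0] == pytest.approx(3 / math.sqrt(2))

    def test_mean_diff_f_as_printed(self):
        x1 = np.array([0.0, 2.0])
        x2 = np.array([3.0, 5.0])
        Z = frame(np.concatenate([x1, x2])[:, None])
        V = dcv_component_matrix(Z, labels(2, 2))
        xb = np.concatenate([x1, x2]).mean()
        expected = (2 * (x1.mean() - xb) ** 2 + 2 * (x2.mean() - xb) ** 2) / \
                   (x1.var(ddof=1) + x2.var(ddof=1))
        assert V.components[0, 1] == pytest.approx(expected)

    def test_brown_forsythe_against_direct(self, rng):
        x1 = rng.normal(size=7)
        x2 = rng.normal(scale=3, size=9)
        Z = frame(np.concatenate([x1, x2])[:, None])
        V = dcv_component_matrix(Z, labels(7, 9))
        b1 = np.abs(x1 - np.median(x1))
        b2 = np.abs(x2 - np.median(x2))
        bb = np.concatenate([b1, b2]).mean()
        num = 7 * (b1.mean() - bb) ** 2 + 9 * (b2.mean() - bb) ** 2
        den = (((b1 - b1.mean()) ** 2).sum() + ((b2 - b2.mean()) ** 2).sum()) / 14
        assert V.components[0, 2] == pytest.approx(num / den)

    @pytest.mark.parametrize("x1,x2,expected", [
        ([1, 2], [3, 4], 1.0),
        ([1, 3], [2, 4], 0.5),
    ])
    def test_ks_hand_values(self, x1, x2, expected):
        Z = frame(np.array(x1 + x2, dtype=float)[:, None])
        V = dcv_component_matrix(Z, labels(2, 2))
        assert V.components[0, 3] == pytest.approx(expected)

    def test_ks_matches_bruteforce_and_scipy(self, rng):
        for _ in range(10):
            n1, n2 = 6, 9
            x = np.concatenate([rng.normal(size=n1), rng.normal(1, 2, n2)])
            V = dcv_component_matrix(frame(x[:, None]), labels(n1, n2))
            assert V.components[0, 3] == pytest.approx(
                ks_bruteforce(x[:n1], x[n1:]))
            assert V.components[0, 3] == pytest.approx(
                ks_2samp(x[:n1], x[n1:]).statistic)

    def test_ks_with_ties(self):
        x = np.array([1.0, 1.0, 2.0, 1.0, 2.0, 2.0])
        V = dcv_component_matrix(frame(x[:, None]), labels(3, 3))
        assert V.components[0, 3] == pytest.approx(
            ks_bruteforce(x[:3], x[3:]))

    def test_info_gain_matches_reference(self, rng):
        for i in range(12):
            n1, n2 = 8, 10
            x = np.concatenate([rng.normal(size=n1),
                                rng.normal(1.5 * (i % 3), 1, n2)])
            y = np.array([0] * n1 + [1] * n2)
            V = dcv_component_matrix(frame(x[:, None]), labels(n1, n2))
            assert V.components[0, 4] == pytest.approx(
                mdl_info_gain_reference(x, y), abs=1e-10)

    def test_info_gain_separable(self):
        x = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        V = dcv_component_matrix(frame(x[:, None]), labels(3, 3))
        assert V.components[0, 4] == pytest.approx(math.log(2))

    def test_equal_frequency_alternative(self, rng):
        x = rng.normal(size=12)
        V = dcv_component_matrix(frame(x[:, None]), labels(6, 6),
                                 discretization=4)
        assert np.isfinite(V.components[0, 4])
        with pytest.raises(ValueError):
            dcv_component_matrix(frame(x[:, None]), labels(6, 6),
                                 discretization="bogus")

    def test_component_ranges(self, rng):
        Z = frame(rng.normal(size=(14, 20)))
        V = dcv_component_matrix(Z, labels(7, 7))
        assert np.all(V.components[:, 1] >= 0)
        assert np.all(V.components[:, 2] >= 0)
        assert np.all((V.components[:, 3] >= 0) & (V.components[:, 3] <= 1))
        assert np.all(V.components[:, 4] >= 0)

    def test_label_swap_invariance(self, rng):
        Z = frame(rng.normal(size=(12, 5)))
        y1 = GroupLabels(np.array(["a"] * 6 + ["b"] * 6))
        y2 = GroupLabels(np.array(["b"] * 6 + ["a"] * 6))
        V1 = dcv_component_matrix(Z, y1)
        V2 = dcv_component_matrix(Z, y2)
        np.testing.assert_allclose(V1.components, V2.components, atol=1e-12)

    def test_requires_two_classes_min_two_each(self, rng):
        Z = frame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            dcv_component_matrix(Z, GroupLabels(np.array(["a", "a", "a", "a", "b"])))

    def test_rejects_nonfinite(self):
        Z = frame(np.array([[1.0], [np.inf], [0.0], [1.0]]))
        with pytest.raises(ValueError, match="finite"):
            dcv_component_matrix(Z, labels(2, 2))


class TestScores:
    def test_zscore_oracle(self, rng):
        comps = rng.normal(size=(100, 5)) ** 2
        V = DCVMatrix(comps, [f"r{i}/x" for i in range(100)])
        out = dcv_scores(V)
        # independent two-pass oracle
        expected = np.zeros(100)
        for k in range(5):
            col = comps[:, k]
            expected += (col - col.mean()) / col.std(ddof=1)
        assert np.max(np.abs(out.scores - expected)) < 1e-10

    def test_identical_rows_equal_scores(self):
        comps = np.vstack([np.arange(5.0)] * 2 + [np.ones(5)])
        out = dcv_scores(DCVMatrix(comps, ["r1/x", "r2/x", "r3/x"]))
        assert out.scores[0] == pytest.approx(out.scores[1])

    def test_constant_column_contributes_zero(self, rng):
        comps = rng.normal(size=(30, 5))
        comps[:, 2] = 7.0
        out = dcv_scores(DCVMatrix(comps, [f"r{i}/x" for i in range(30)]))
        assert np.allclose(out.standardized[:, 2], 0.0)

    def test_single_ratio_warns_zero(self):
        V = DCVMatrix(np.ones((1, 5)), ["r/x"])
        with pytest.warns(UserWarning):
            out = dcv_scores(V)
        assert out.scores[0] == 0.0

    def test_standardized_moments(self, rng):
        comps = rng.normal(size=(50, 5))
        out = dcv_scores(DCVMatrix(comps, [f"r{i}/x" for i in range(50)]))
        np.testing.assert_allclose(out.standardized.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.standardized.std(axis=0, ddof=1), 1,
                                   atol=1e-12)
        assert out.scores.mean() == pytest.approx(0, abs=1e-10)

    def test_ranked_ordering_stable(self):
        comps = np.zeros((3, 5))
        out = dcv_scores(DCVMatrix(comps, ["b/x", "a/x", "c/x"]))
        assert [r for r, _ in out.ranked()] == ["a/x", "b/x", "c/x"]


class TestOrientationInvariance:
    def test_negating_column_keeps_score(self, rng):
        vals = rng.normal(size=(16, 6))
        ratios = [(f"n{i}", f"d{i}") for i in range(6)]
        y = labels(8, 8)
        Z1 = LogratioFrame(vals, ratios)
        flipped = vals.copy()
        flipped[:, 2] *= -1
        Z2 = LogratioFrame(flipped, [(("d2", "n2") if i == 2 else r)
                                     for i, r in enumerate(ratios)])
        s1 = dcv_scores(dcv_component_matrix(Z1, y))
        s2 = dcv_scores(dcv_component_matrix(Z2, y))
        np.testing.assert_allclose(s1.scores, s2.scores, atol=1e-9)
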
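import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from selenergy import (DistanceMatrix, GroupLabels, LogratioFrame, anosim_r,
                       combined_f_raw, disco_f, dispersion_detected,
                       energy_statistic, euclidean_distances, permanova_f,
                       permdisp_f, scaled_combined_f, spatial_median)
from selenergy.permutation import generate_permutations, PermutationScheme


def frame(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return LogratioFrame(values, [(f"n{i}", f"d{i}")
                                  for i in range(values.shape[1])])


def labels(n1, n2):
    return GroupLabels(np.array(["g1"] * n1 + ["g2"] * n2))


class TestEuclideanDistances:
    def test_1d_points(self):
        D = euclidean_distances(frame([[0.0], [3.0]]))
        assert D.values[0, 1] == pytest.approx(3.0)

    def test_duplicate_rows(self):
        D = euclidean_distances(frame([[1.0, 2.0], [1.0, 2.0]]))
        assert D.values[0, 1] == 0.0

    def test_double_loop_oracle(self, rng):
        X = rng.normal(size=(10, 4))
        D = euclidean_distances(frame(X))
        for i in range(10):
            for j in range(10):
                assert D.values[i, j] == pytest.approx(
                    np.linalg.norm(X[i] - X[j]), abs=1e-10)


class TestDisco:
    @staticmethod
    def disco_oracle(D, codes, alpha):
        """Explicit double-sum DISCO decomposition for two groups."""
        A = D ** alpha
        n = len(codes)
        g0 = np.nonzero(codes == 0)[0]
        g1 = np.nonzero(codes == 1)[0]
        total = (n / 2) * A.mean()
        w = 0.0
        for g in (g0, g1):
            w += (len(g) / 2) * A[np.ix_(g, g)].mean()
        s = total - w
        return s, w, s / (w / (n - 2))

    def test_relabel_invariance(self, rng):
        X = rng.normal(size=(10, 3))
        D = euclidean_distances(frame(X))
        f1 = disco_f(D, labels(5, 5))
        y_swapped = GroupLabels(np.array(["g2"] * 5 + ["g1"] * 5))
        f2 = disco_f(D, y_swapped)
        assert f1.value == pytest.approx(f2.value)

    def test_four_point_oracle(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = euclidean_distances(frame(X))
        st = disco_f(D, labels(2, 2), alpha=1.0)
        s, w, f = self.disco_oracle(D.values, np.array([0, 0, 1, 1]), 1.0)
        assert st.parts["S"] == pytest.approx(s)
        assert st.parts["W"] == pytest.approx(w)
        assert st.value == pytest.approx(f)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_conservation(self, rng, alpha):
        for _ in range(10):
            X = rng.normal(size=(12, 4))
            D = euclidean_distances(frame(X))
            st = disco_f(D, labels(5, 7), alpha=alpha)
            assert st.parts["S"] + st.parts["W"] == pytest.approx(
                st.parts["total"], abs=1e-10)

    def test_alpha2_proportional_to_anova_partition(self, rng):
        # with alpha=2 the energy partition reduces to the squared-distance one
        x = rng.normal(size=(9, 1))
        D = euclidean_distances(frame(x))
        st = disco_f(D, labels(4, 5), alpha=2.0)
        pf = permanova_f(D, labels(4, 5))
        assert st.parts["S"] == pytest.approx(pf.parts["SS_A"])
        assert st.parts["W"] == pytest.approx(pf.parts["SS_W"])

    def test_group_size_validation(self, rng):
        X = rng.normal(size=(4, 2))
        D = euclidean_distances(frame(X))
        with pytest.raises(ValueError):
            disco_f(D, GroupLabels(np.array(["a", "b", "b", "b"])))


class TestEnergy:
    def test_identical_clouds_zero(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        D = euclidean_distances(frame(X))
        assert energy_statistic(D, labels(2, 2)).value == pytest.approx(0.0)

    def test_singleton_hand_value(self):
        D = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        y = GroupLabels(np.array(["a", "b"]))
        assert energy_statistic(D, y).value == pytest.approx(1.0)

    def test_nonnegative_on_random_metric_data(self, rng):
        for _ in range(15):
            X = rng.normal(size=(11, 3))
            D = euclidean_distances(frame(X))
            assert energy_statistic(D, labels(5, 6)).value >= -1e-10


class TestPermanova:
    def test_hand_value_200(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        st = permanova_f(euclidean_distances(frame(X)), labels(2, 2))
        assert st.parts["SS_T"] == pytest.approx(101.0)
        assert st.parts["SS_A"] == pytest.approx(100.0)
        assert st.parts["SS_W"] == pytest.approx(1.0)
        assert st.value == pytest.approx(200.0)

    def test_partition_identity(self, rng):
        X = rng.normal(size=(14, 5))
        st = permanova_f(euclidean_distances(frame(X)), labels(6, 8))
        assert st.parts["SS_A"] + st.parts["SS_W"] == pytest.approx(
            st.parts["SS_T"], abs=1e-10)

    def test_matches_skbio(self, rng):
        X = rng.normal(size=(16, 4))
        D = euclidean_distances(frame(X))
        st = permanova_f(D, labels(7, 9))
        sk = skbio_permanova(SkbioDM(D.values), ["a"] * 7 + ["b"] * 9,
                             permutations=0)
        assert st.value == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_permutation_null_mean_near_one(self, rng):
        X = rng.normal(size=(20, 3))
        D = euclidean_distances(frame(X))
        vals = []
        for _ in range(300):
            perm = rng.permutation(np.array(["a"] * 10 + ["b"] * 10))
            vals.append(permanova_f(D, GroupLabels(perm)).value)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_zero_within_sentinel(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        st = permanova_f(euclidean_distances(frame(X)), labels(2, 2))
        assert st.value == np.inf
        assert st.parts["zero_within"]

    def test_multigroup(self, rng):
        X = rng.normal(size=(12, 3))
        y = GroupLabels(np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4))
        st = permanova_f(euclidean_distances(frame(X)), y)
        sk = skbio_permanova(SkbioDM(euclidean_distances(frame(X)).values),
                             ["a"] * 4 + ["b"] * 4 + ["c"] * 4, permutations=0)
        assert st.value == pytest.approx(sk["test statistic"], rel=1e-9)


class TestSpatialMedianAndDispersion:
    def test_symmetric_point_set(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        med = spatial_median(X)
        np.testing.assert_allclose(med, [0.0, 0.0], atol=1e-7)

    def test_nonconvergence_error(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(RuntimeError, match="iterations"):
            spatial_median(X, tol=0.0, max_iter=3)

    def test_equal_residuals_small_f(self, rng):
        base = rng.normal(size=(15, 3))
        X = np.vstack([base, base + 100.0])  # same shape, shifted center
        st = permdisp_f(frame(X), labels(15, 15))
        assert st.value == pytest.approx(0.0, abs=1e-8)

    def test_spread_difference_detected(self, rng):
        X = np.vstack([rng.normal(scale=1, size=(20, 3)),
                       rng.normal(scale=10, size=(20, 3))])
        y = labels(20, 20)
        obs = permdisp_f(frame(X), y).value
        null = []
        for _ in range(99):
            perm = rng.permutation(y.labels)
            null.append(permdisp_f(frame(X), GroupLabels(perm)).value)
        assert obs > np.percentile(null, 95)


class TestCombinedF:
    def test_parts_recombine(self, rng):
        X = rng.normal(size=(16, 4))
        st = combined_f_raw(frame(X), labels(8, 8))
        assert st.value == st.parts["F_location"] + st.parts["F_dispersion"]

    def test_location_shift_dominates_location_part(self, rng):
        X = np.vstack([rng.normal(size=(15, 3)),
                       rng.normal(loc=8.0, size=(15, 3))])
        st = combined_f_raw(frame(X), labels(15, 15))
        assert st.parts["F_location"] > 10 * max(st.parts["F_dispersion"], 1.0)

    def test_dispersion_shift_dominates_dispersion_part(self, rng):
        X = np.vstack([rng.normal(scale=1, size=(15, 3)),
                       rng.normal(scale=10, size=(15, 3))])
        st = combined_f_raw(frame(X), labels(15, 15))
        assert st.parts["F_dispersion"] > 10 * st.parts["F_location"]


class TestScaledCombinedF:
    def _perms(self, y, m, seed):
        return generate_permutations(y, PermutationScheme(k=m, seed=seed))

    def test_requires_30_permutations(self, rng):
        X = rng.normal(size=(10, 2))
        y = labels(5, 5)
        with pytest.raises(ValueError, match="30"):
            scaled_combined_f(frame(X), y, self._perms(y, 10, 0))

    def test_null_data_near_zero(self, rng):
        X = rng.normal(size=(24, 3))
        y = labels(12, 12)
        st = scaled_combined_f(frame(X), y, self._perms(y, 200, 1))
        assert abs(st.value) < 4.0  # a couple of null sds

    def test_strong_signal_exceeds_null(self, rng):
        X = np.vstack([rng.normal(size=(15, 3)),
                       rng.normal(loc=6, scale=4, size=(15, 3))])
        y = labels(15, 15)
        st = scaled_combined_f(frame(X), y, self._perms(y, 100, 2))
        assert st.value > 5.0

    def test_deterministic_given_permutation_set(self, rng):
        X = rng.normal(size=(20, 3))
        y = labels(10, 10)
        perms = self._perms(y, 60, 3)
        a = scaled_combined_f(frame(X), y, perms).value
        b = scaled_combined_f(frame(X), y, perms).value
        assert a == b

    def test_doubling_m_shrinks_mc_sd(self, rng):
        X = np.vstack([rng.normal(size=(10, 2)),
                       rng.normal(loc=1.0, size=(10, 2))])
        y = labels(10, 10)

        def mc_sd(m, reps):
            vals = [scaled_combined_f(frame(X), y,
                                      self._perms(y, m, 100 + r)).value
                    for r in range(reps)]
            return np.std(vals, ddof=1)

        sd_small = mc_sd(40, 20)
        sd_large = mc_sd(160, 20)
        assert sd_large < sd_small  # ~2x expected; direction must hold


class TestDispersionDetected:
    def test_minimum_k(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            dispersion_detected(frame(X), labels(5, 5), k=10)

    def test_strong_dispersion_detected(self, rng):
        hits = 0
        for r in range(10):
            X = np.vstack([rng.normal(scale=1, size=(40, 3)),
                           rng.normal(scale=10, size=(40, 3))])
            hits += dispersion_detected(frame(X), labels(40, 40), k=99,
                                        rng=np.random.default_rng(r))
        assert hits == 10

    def test_null_rate_near_alpha(self, rng):
        hits = 0
        reps = 40
        for r in range(reps):
            X = rng.normal(size=(20, 3))
            hits += dispersion_detected(frame(X), labels(10, 10), k=99,
                                        rng=np.random.default_rng(1000 + r))
        # binomial(40, 0.05): P(X > 7) < 1e-3
        assert hits <= 7


class TestAnosim:
    def test_complete_separation(self):
        X = np.array([[0.0], [1.0], [100.0], [101.0]])
        st = anosim_r(euclidean_distances(frame(X)), labels(2, 2))
        assert st.value == pytest.approx(1.0)

    def test_bounds_and_null_mean(self, rng):
        X = rng.normal(size=(14, 3))
        D = euclidean_distances(frame(X))
        vals = []
        for _ in range(200):
            perm = rng.permutation(np.array(["a"] * 7 + ["b"] * 7))
            r = anosim_r(D, GroupLabels(perm)).value
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
            vals.append(r)
        assert abs(np.mean(vals)) < 0.05

    def test_matches_skbio(self, rng):
        X = rng.normal(size=(12, 3))
        D = euclidean_distances(frame(X))
        st = anosim_r(D, labels(5, 7))
        sk = skbio_anosim(SkbioDM(D.values), ["a"] * 5 + ["b"] * 7,
                          permutations=0)
        assert st.value == pytest.approx(sk["test statistic"], rel=1e-9)


class TestDistanceMatrixValidation:
    def test_symmetry_enforced(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(bad)

    def test_diagonal_enforced(self):
        bad = np.array([[0.1, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(bad)

    def test_reorder_invariance(self, rng):
        X = rng.normal(size=(10, 3))
        perm = rng.permutation(10)
        y = np.array(["a"] * 5 + ["b"] * 5)
        st1 = permanova_f(euclidean_distances(frame(X)), GroupLabels(y))
        st2 = permanova_f(euclidean_distances(frame(X[perm])),
                          GroupLabels(y[perm]))
        assert st1.value == pytest.approx(st2.value, rel=1e-10)
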
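import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from asmbly.core_data import AsvTable
from asmbly.diversity import (Permanova, beta_matrix, chao1, hier_partition,
                              mantel, permanova)


class TestChao1:
    def test_no_singletons_returns_observed(self):
        counts = np.array([3, 5, 2, 0, 7])
        assert chao1(counts, bias_corrected=False) == 4

    def test_hand_formula_classic(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 16/4 = 14
        counts = np.array([1, 1, 1, 1, 2, 2, 3, 4, 5, 6])
        assert chao1(counts, bias_corrected=False) == 14.0

    def test_hand_formula_bias_corrected(self):
        # 10 + 4*3/(2*3) = 12
        counts = np.array([1, 1, 1, 1, 2, 2, 3, 4, 5, 6])
        assert chao1(counts, bias_corrected=True) == 12.0

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            assert chao1(np.zeros(5)) == 0.0

    def test_at_least_observed_richness(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 5, size=30)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum() - 1e-9


class TestBetaMatrix:
    def test_bray_hand_formula(self):
        t = AsvTable(np.array([[1, 2, 3], [3, 2, 1]]), ["x", "y"],
                     ["a", "b", "c"])
        dm = beta_matrix(t, "bray_curtis")
        assert np.isclose(dm["x", "y"], 4 / 12)

    def test_jaccard_hand_formula(self):
        # {a,b,c} vs {b,c,d}: 1 - 2/4 = 0.5
        t = AsvTable(np.array([[1, 1, 1, 0], [0, 5, 2, 3]]), ["x", "y"],
                     ["a", "b", "c", "d"])
        dm = beta_matrix(t, "jaccard_binary")
        assert np.isclose(dm["x", "y"], 0.5)

    def test_identical_samples_zero(self):
        t = AsvTable(np.array([[2, 3], [2, 3]]), ["x", "y"], ["a", "b"])
        for metric in ("bray_curtis", "jaccard_binary"):
            assert beta_matrix(t, metric)["x", "y"] == 0.0

    def test_valid_distance_matrix(self, rng):
        counts = rng.integers(0, 20, size=(6, 15))
        counts[:, 0] += 1  # avoid empty samples
        t = AsvTable(counts, [f"s{i}" for i in range(6)],
                     [f"a{i}" for i in range(15)])
        for metric in ("bray_curtis", "jaccard_binary"):
            dm = beta_matrix(t, metric)
            d = np.asarray(dm.data)
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            assert (d >= 0).all() and (d <= 1).all()

    def test_unknown_metric(self, small_table):
        with pytest.raises(ValueError):
            beta_matrix(small_table, "unifrac")


def _brute_force_permanova_p(d2, labels):
    """Independent exhaustive enumeration of the label permutations."""
    def f_stat(lab):
        n = len(lab)
        groups = [np.flatnonzero(lab == g) for g in np.unique(lab)]
        a = len(groups)
        ss_t = d2.sum() / (2 * n)
        ss_w = sum(d2[np.ix_(g, g)].sum() / (2 * len(g)) for g in groups)
        return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(labels)
    count = total = 0
    for perm in itertools.permutations(range(len(labels))):
        count += f_stat(labels[list(perm)]) >= f_obs - 1e-12
        total += 1
    return f_obs, count / total


class TestPermanova:
    def test_equidistant_points_f_is_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = permanova(DistanceMatrix(d, ids=list("abcd")),
                        ["g1", "g1", "g2", "g2"], method="exact")
        assert np.isclose(res.pseudo_F, 1.0)
        assert res.p_value == 1.0  # every split is equivalent

    def test_exact_p_matches_brute_force(self, rng):
        for trial in range(3):
            pts = rng.normal(size=(7, 3))
            d = squareform(pdist(pts))
            labels = np.array(["a", "a", "a", "b", "b", "c", "c"])
            res = permanova(DistanceMatrix(d, ids=[str(i) for i in range(7)]),
                            labels, method="exact")
            f_ref, p_ref = _brute_force_permanova_p(d ** 2, labels)
            assert np.isclose(res.pseudo_F, f_ref)
            assert np.isclose(res.p_value, p_ref)

    def test_r2_invariant_under_relabeling(self, rng):
        pts = rng.normal(size=(10, 4))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[str(i) for i in range(10)])
        g1 = np.array(["u"] * 5 + ["v"] * 5)
        g2 = np.array(["v"] * 5 + ["u"] * 5)  # names swapped
        r1 = permanova(dm, g1, n_perm=9, seed=0)
        r2 = permanova(dm, g2, n_perm=9, seed=0)
        assert np.isclose(r1.R2, r2.R2)
        assert np.isclose(r1.pseudo_F, r2.pseudo_F)

    def test_strong_separation_minimal_p(self, rng):
        pts = rng.normal(size=(12, 3), scale=0.01)
        pts[6:] += 100.0
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[str(i) for i in range(12)])
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=1)
        assert res.p_value == 1 / 200

    def test_agrees_with_skbio(self, rng):
        pts = rng.normal(size=(12, 5))
        pts[6:] += 1.0
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[str(i) for i in range(12)])
        groups = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, groups, n_perm=999, seed=5)
        ref = skbio_permanova(dm, pd.DataFrame({"g": groups}, index=dm.ids),
                              column="g", permutations=999)
        assert np.isclose(mine.pseudo_F, ref["test statistic"])
        assert abs(mine.p_value - ref["p-value"]) < 0.05

    def test_single_group_rejected(self, rng):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            Permanova(dm, ["g", "g", "g"])


class TestMantel:
    def _dm(self, rng, n=8):
        pts = rng.normal(size=(n, 3))
        return DistanceMatrix(squareform(pdist(pts)),
                              ids=[str(i) for i in range(n)])

    def test_self_correlation_is_one(self, rng):
        dm = self._dm(rng)
        r, p = mantel(dm, dm, n_perm=99, seed=0)
        assert np.isclose(r, 1.0)
        assert p == 1 / 100

    def test_constant_matrix_nan(self, rng):
        dm = self._dm(rng)
        const = DistanceMatrix(np.ones((8, 8)) - np.eye(8), ids=dm.ids)
        with pytest.warns(UserWarning):
            r, p = mantel(dm, const, n_perm=9)
        assert np.isnan(r)

    def test_size_mismatch(self, rng):
        with pytest.raises(ValueError):
            mantel(self._dm(rng, 8), self._dm(rng, 6))

    def test_type_one_error_controlled(self, rng):
        """Independent distance structures reject at ~alpha."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            d1 = self._dm(rng)
            d2 = self._dm(rng)
            _, p = mantel(d1, d2, n_perm=99,
                          seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert 0.01 <= rejections / n_rep <= 0.09


class TestHierPartition:
    def test_single_predictor_equals_model_r2(self, rng):
        f = pd.DataFrame({"g": ["a", "a", "b", "b"] * 4})
        y = (f["g"] == "a") * 2 + rng.normal(0, 0.3, 16)
        res = hier_partition(y, f)
        assert np.isclose(res.independent["g"], res.full_r2)

    def test_orthogonal_factors_get_marginal_r2(self, rng):
        f1 = np.tile(["x", "y"], 8)
        f2 = np.repeat(["u", "v"], 8)
        y = (f1 == "x") * 1.0 + (f2 == "u") * 2.0 + rng.normal(0, 0.05, 16)
        factors = pd.DataFrame({"f1": f1, "f2": f2})
        res = hier_partition(y, factors)
        m1 = hier_partition(y, factors[["f1"]]).full_r2
        m2 = hier_partition(y, factors[["f2"]]).full_r2
        assert np.isclose(res.independent["f1"], m1, atol=1e-10)
        assert np.isclose(res.independent["f2"], m2, atol=1e-10)

    def test_contributions_sum_to_full_r2(self, rng):
        factors = pd.DataFrame({
            "a": rng.choice(["p", "q"], 40),
            "b": rng.choice(["r", "s", "t"], 40),
            "c": rng.choice(["u", "v"], 40),
        })
        y = rng.normal(size=40) + (factors["a"] == "p") * 0.5
        res = hier_partition(y, factors)
        assert np.isclose(res.independent.sum(), res.full_r2, atol=1e-10)

    def test_degenerate_factor_rejected(self):
        f = pd.DataFrame({"g": ["a"] * 6})
        with pytest.raises(ValueError, match="fewer than 2"):
            hier_partition(np.arange(6.0), f)
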
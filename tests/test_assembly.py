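import numpy as np
import pytest

from asmbly.assembly import BetaNTI, bmntd, stochastic_fraction
from asmbly.core_data import AsvTable, cophenetic_matrix
from asmbly.synth import simulate_tree


def brute_force_bmntd(counts_k, counts_m, dist, weighted=True):
    """Independent double-loop betaMNTD for one community pair."""
    def half(src, dst):
        present_dst = np.flatnonzero(dst > 0)
        total = 0.0
        if weighted:
            weights = src / src.sum()
        else:
            pres = src > 0
            weights = pres / pres.sum()
        for i in np.flatnonzero(src > 0):
            total += weights[i] * min(dist[i, j] for j in present_dst)
        return total

    return 0.5 * (half(counts_k, counts_m) + half(counts_m, counts_k))


class TestBmntd:
    def test_identical_communities_zero(self):
        tree = simulate_tree(5, seed=0)
        t = AsvTable(np.array([[1, 2, 0, 3, 0]] * 2), ["x", "y"],
                     [f"ASV_{i+1}" for i in range(5)])
        assert np.isclose(bmntd(t, tree).iloc[0, 1], 0.0)

    def test_two_singleton_communities(self):
        tree = simulate_tree(2, seed=1)
        d = cophenetic_matrix(tree, ["ASV_1", "ASV_2"])
        t = AsvTable(np.array([[4, 0], [0, 9]]), ["x", "y"],
                     ["ASV_1", "ASV_2"])
        assert np.isclose(bmntd(t, tree).iloc[0, 1], d[0, 1])

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted, rng):
        tree = simulate_tree(6, seed=3)
        ids = [f"ASV_{i+1}" for i in range(6)]
        dist = cophenetic_matrix(tree, ids)
        for _ in range(20):
            counts = rng.integers(0, 6, size=(3, 6))
            counts[counts.sum(axis=1) == 0, 0] = 1
            t = AsvTable(counts, ["x", "y", "z"], ids)
            mat = bmntd(t, tree, weighted=weighted)
            for a, b in [(0, 1), (0, 2), (1, 2)]:
                ref = brute_force_bmntd(counts[a], counts[b], dist, weighted)
                assert np.isclose(mat.iloc[a, b], ref, atol=1e-12)

    def test_missing_tip_named_in_error(self):
        tree = simulate_tree(3, seed=0)
        t = AsvTable(np.array([[1, 1]]), ["x"], ["ASV_1", "missing_taxon"])
        with pytest.raises(KeyError, match="missing_taxon"):
            bmntd(t, tree)

    def test_scales_linearly_with_branch_lengths(self, rng):
        tree = simulate_tree(10, seed=4)
        ids = [f"ASV_{i+1}" for i in range(10)]
        counts = rng.integers(0, 5, size=(4, 10)) + \
            (rng.random((4, 10)) < 0.2)
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = AsvTable(counts, list("wxyz"), ids)
        base = bmntd(t, tree).to_numpy()
        scaled_tree = tree.copy()
        for node in scaled_tree.traverse(include_self=False):
            node.length *= 3.0
        assert np.allclose(bmntd(t, scaled_tree).to_numpy(), 3.0 * base)


@pytest.fixture(scope="module")
def fitted():
    tree = simulate_tree(40, seed=5)
    rng = np.random.default_rng(6)
    p = rng.lognormal(0, 1.5, 40)
    p /= p.sum()
    counts = rng.multinomial(150, p, size=6)  # sparse: real taxon turnover
    t = AsvTable(counts, [f"s{i}" for i in range(6)],
                 [f"ASV_{i+1}" for i in range(40)])
    return BetaNTI(t, tree), t, tree


class TestBetaNTI:

    def test_bit_reproducible(self, fitted):
        model, *_ = fitted
        a = model.fit(n_rand=99, seed=11)
        b = model.fit(n_rand=99, seed=11)
        assert np.array_equal(a.bnti.to_numpy(), b.bnti.to_numpy())

    def test_zscore_definition(self, fitted):
        model, *_ = fitted
        res = model.fit(n_rand=99, seed=1)
        i, j = 0, 3
        expected = (res.bmntd_obs.iat[i, j] - res.null_mean.iat[i, j]) \
            / res.null_sd.iat[i, j]
        assert np.isclose(res.bnti.iat[i, j], expected)

    def test_invariant_to_branch_scaling(self, fitted):
        """The z-score cancels a uniform branch-length factor exactly."""
        model, t, tree = fitted
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length *= 5.0
        a = model.fit(n_rand=99, seed=2).bnti.to_numpy()
        b = BetaNTI(t, scaled).fit(n_rand=99, seed=2).bnti.to_numpy()
        assert np.allclose(a, b, atol=1e-9)

    def test_shuffle_preserves_distance_multiset(self, fitted):
        model, *_ = fitted
        rng = np.random.default_rng(0)
        perm = rng.permutation(model._dist.shape[0])
        shuffled = model._dist[np.ix_(perm, perm)]
        assert np.allclose(np.sort(shuffled, axis=None),
                           np.sort(model._dist, axis=None))

    def test_low_n_rand_warns(self, fitted):
        model, *_ = fitted
        with pytest.warns(UserWarning, match="low"):
            model.fit(n_rand=9, seed=0)

    def test_null_draws_retained_on_request(self, fitted):
        model, *_ = fitted
        res = model.fit(n_rand=49, seed=3, keep_null_draws=True)
        assert res.null_draws.shape == (49, 6, 6)
        assert np.allclose(res.null_draws.mean(axis=0),
                           res.null_mean.to_numpy())


class TestStochasticFraction:
    def _result(self, values):
        n = values.shape[0]
        import pandas as pd
        from asmbly.assembly import BetaNtiResult
        df = pd.DataFrame(values)
        return BetaNtiResult(bnti=df, bmntd_obs=df, null_mean=df,
                             null_sd=df, n_randomizations=1)

    def test_all_deterministic(self):
        v = np.full((3, 3), 3.0)
        np.fill_diagonal(v, 0)
        assert stochastic_fraction(self._result(v)) == 0.0

    def test_all_stochastic(self):
        assert stochastic_fraction(self._result(np.zeros((3, 3)))) == 1.0

    def test_hand_count(self):
        v = np.zeros((4, 4))
        vals = [-3.0, -1.0, 0.0, 2.5, -3.0, 2.5]
        iu = np.triu_indices(4, 1)
        v[iu] = vals
        v = v + v.T
        # |bnti| < 2 for {-1, 0} of {-3,-1,0,2.5,-3,2.5} -> 2/6
        assert np.isclose(stochastic_fraction(self._result(v)), 2 / 6)

    def test_nan_pairs_excluded_with_warning(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = np.nan
        v[0, 2] = v[2, 0] = 3.0
        with pytest.warns(UserWarning, match="excluded"):
            frac = stochastic_fraction(self._result(v))
        assert np.isclose(frac, 0.5)

    def test_all_nan_is_error(self):
        v = np.full((2, 2), np.nan)
        with pytest.raises(ValueError):
            stochastic_fraction(self._result(v))
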
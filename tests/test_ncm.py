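import numpy as np
import pytest
from scipy import integrate, stats

from asmbly.core_data import AsvTable
from asmbly.ncm import SloanNCM, compare_fits, fit_ncm, ncm_predict
from asmbly.synth import assemble_neutral, simulate_metacommunity


class TestNcmPredict:
    def test_large_nm_step_function(self):
        d = 0.01
        assert ncm_predict(0.05, 1e7, d) > 0.999
        assert ncm_predict(0.001, 1e7, d) < 1e-6

    def test_symmetry_at_half(self):
        # p = d = 0.5 makes Beta(a, a) symmetric about 1/2
        assert np.isclose(ncm_predict(0.5, 123.0, 0.5), 0.5)

    def test_quadrature_oracle(self):
        """The prediction equals direct numerical integration of the Beta
        density above the detection limit."""
        nm, d, p = 500.0, 1 / 2000, 0.001
        a, b = nm * p, nm * (1 - p)
        val, _ = integrate.quad(lambda x: stats.beta.pdf(x, a, b), d, 1,
                                limit=200)
        assert np.isclose(ncm_predict(p, nm, d), val, atol=1e-8)

    def test_monotone_in_p(self):
        grid = np.linspace(1e-5, 0.2, 100)
        pred = ncm_predict(grid, 300.0, 1 / 1000)
        assert (np.diff(pred) >= -1e-12).all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_rejects_bad_p(self, bad):
        with pytest.raises(ValueError):
            ncm_predict(bad, 100.0, 0.001)


class TestFitNcm:
    def test_neutral_parameter_recovery(self):
        """Data simulated at N*m = 500 is fitted back within tolerance."""
        p = simulate_metacommunity(300, sigma_log=1.5, seed=0)
        table = assemble_neutral(p, 2000, 0.25, 200, seed=1)
        fit = fit_ncm(table)
        assert abs(fit.Nm / 500 - 1) < 0.25
        assert fit.R2 > 0.6

    def test_self_consistent_frequencies(self):
        """If observed frequencies are set exactly to the model prediction,
        the fit recovers the generating N*m and R2 = 1."""
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(1e-4, 0.05, 100))
        model = SloanNCM.__new__(SloanNCM)
        model.N = 2000.0
        model.d = 1 / 2000
        model.p = p
        model.freq = ncm_predict(p, 700.0, model.d)
        model.asv_ids = [f"a{i}" for i in range(100)]
        model.table = assemble_neutral(p / p.sum(), 100, 0.5, 3, seed=0)
        fit = model.fit()
        assert abs(fit.Nm - 700.0) < 1.0
        assert fit.R2 > 0.999999

    def test_duplicating_samples_keeps_nm(self):
        p = simulate_metacommunity(150, sigma_log=1.5, seed=5)
        table = assemble_neutral(p, 1000, 0.3, 50, seed=6)
        doubled = AsvTable(np.vstack([table.counts, table.counts]),
                           [f"{s}_{k}" for k in "ab" for s in table.sample_ids],
                           table.asv_ids)
        f1, f2 = fit_ncm(table), fit_ncm(doubled)
        assert np.isclose(f1.Nm, f2.Nm, rtol=1e-6)

    def test_r2_can_be_negative(self):
        """A frequency pattern anti-correlated with abundance must yield a
        negative R2, reported unclipped (no nonnegative-occupancy curve can
        beat the mean on decreasing data)."""
        model = SloanNCM.__new__(SloanNCM)
        model.N = 2000.0
        model.d = np.log(2) / 2000
        model.p = np.logspace(-4, -1, 50)
        model.freq = np.linspace(0.95, 0.05, 50)  # decreasing in p
        model.asv_ids = [f"a{i}" for i in range(50)]
        model.table = assemble_neutral(
            simulate_metacommunity(50, seed=0), 100, 0.5, 3, seed=0)
        fit = model.fit()
        assert fit.R2 < 0

    def test_partition_consistent_with_bands(self):
        p = simulate_metacommunity(200, sigma_log=1.5, seed=9)
        fit = fit_ncm(assemble_neutral(p, 2000, 0.25, 60, seed=10))
        taxa = fit.taxa
        above = taxa["partition"] == "above"
        below = taxa["partition"] == "below"
        assert (taxa.loc[above, "freq"] > taxa.loc[above, "hi"]).all()
        assert (taxa.loc[below, "freq"] < taxa.loc[below, "lo"]).all()


class TestCompareFits:
    def test_self_comparison_all_zero(self):
        p = simulate_metacommunity(100, seed=1)
        fit = fit_ncm(assemble_neutral(p, 1000, 0.5, 40, seed=2))
        out = compare_fits(fit, fit)
        assert np.allclose(out.loc["delta"].astype(float), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_selection_lowers_fit_quality(self, seed):
        """Habitat-varying selection breaks the single-curve relationship
        between abundance and occupancy, so the neutral fit degrades
        relative to a matched neutral community. (A selection pressure
        shared by every sample merely reshapes the pool and stays
        invisible to the fit, which estimates the pool from the data.)"""
        from asmbly.synth import (assemble_selective, brownian_traits,
                                  selection_weights, simulate_tree)
        p = simulate_metacommunity(200, sigma_log=1.5, seed=seed)
        neutral = fit_ncm(assemble_neutral(p, 2000, 0.25, 60,
                                           seed=100 + seed))
        tree = simulate_tree(200, seed=seed)
        ids = [f"ASV_{i+1}" for i in range(200)]
        tv = brownian_traits(tree, seed=seed + 1).reindex(ids).to_numpy()
        w1 = selection_weights(tv, np.quantile(tv, 0.9), 5.0)
        w2 = selection_weights(tv, np.quantile(tv, 0.1), 5.0)
        t1 = assemble_selective(p, 2000, w1, 30, seed=200 + seed,
                                migration_m=0.05)
        t2 = assemble_selective(p, 2000, w2, 30, seed=300 + seed,
                                migration_m=0.05)
        both = AsvTable(np.vstack([t1.counts, t2.counts]),
                        [f"x{i}" for i in range(60)], t1.asv_ids)
        selective = fit_ncm(both)
        out = compare_fits(neutral, selective, labels=("neutral", "sel"))
        assert out.loc["delta", "R2"] > 0
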
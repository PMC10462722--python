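import numpy as np
import pytest

from asmbly.synth import (STAGES, SynthConfig, assemble_neutral,
                          assemble_selective, brownian_traits,
                          simulate_dataset, simulate_metacommunity,
                          simulate_tree)
from asmbly.core_data import cophenetic_matrix


class TestSimulateTree:
    def test_two_tips_cophenetic(self):
        tree = simulate_tree(2, seed=1)
        tips = list(tree.tips())
        assert len(tips) == 2
        d = cophenetic_matrix(tree, [t.name for t in tips])
        assert np.isclose(d[0, 1], tips[0].length + tips[1].length)

    def test_deterministic_newick(self):
        a = str(simulate_tree(50, seed=7))
        b = str(simulate_tree(50, seed=7))
        assert a == b

    def test_cophenetic_is_metric(self, rng):
        tree = simulate_tree(100, seed=2)
        ids = [f"ASV_{i+1}" for i in range(100)]
        d = cophenetic_matrix(tree, ids)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for _ in range(1000):
            i, j, k = rng.choice(100, 3, replace=False)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_rejects_tiny_trees(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestMetacommunity:
    def test_sums_to_one(self):
        p = simulate_metacommunity(500, sigma_log=2, seed=0)
        assert np.isclose(p.sum(), 1.0)
        assert (p > 0).all()

    def test_sigma_zero_is_uniform(self):
        p = simulate_metacommunity(10, sigma_log=0)
        assert np.allclose(p, 0.1)

    def test_lognormal_dominance(self):
        """A wide lognormal SAD spans orders of magnitude in abundance."""
        p = simulate_metacommunity(1000, sigma_log=2, seed=3)
        assert p.max() / p.min() > 100


class TestAssembleNeutral:
    def test_full_migration_tracks_metacommunity(self):
        """With m=1 and large N, mean sample frequencies converge to p."""
        p = simulate_metacommunity(50, sigma_log=1, seed=1)
        t = assemble_neutral(p, 100_000, 1.0, 100, seed=2)
        est = t.relative_abundance().mean(axis=0)
        big = p > 0.01
        assert np.abs(est[big] / p[big] - 1).max() < 0.02

    def test_degenerate_single_taxon(self):
        p = np.array([1.0, 0.0, 0.0])
        t = assemble_neutral(p, 100, 0.5, 5, seed=0)
        assert (t.counts[:, 0] == 100).all()

    def test_seed_reproducible(self):
        p = simulate_metacommunity(30, seed=5)
        a = assemble_neutral(p, 500, 0.3, 4, seed=9)
        b = assemble_neutral(p, 500, 0.3, 4, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_invalid_migration(self):
        with pytest.raises(ValueError):
            assemble_neutral(np.array([0.5, 0.5]), 100, 0.0, 2)


class TestAssembleSelective:
    def test_zero_strength_matches_neutral_probabilities(self):
        """With all fitness weights equal, sampling probabilities reduce
        to the metacommunity p."""
        p = simulate_metacommunity(40, sigma_log=1, seed=4)
        t = assemble_selective(p, 200_000, np.ones(40), 50, seed=1)
        est = t.relative_abundance().mean(axis=0)
        big = p > 0.02
        assert np.abs(est[big] / p[big] - 1).max() < 0.05

    def test_strong_selection_favors_clade(self):
        """Strong stabilizing selection at one clade's trait mean leaves
        that clade holding nearly all reads."""
        tree = simulate_tree(60, seed=11)
        traits = brownian_traits(tree, 1.0, seed=12)
        ids = [f"ASV_{i+1}" for i in range(60)]
        tv = traits.reindex(ids).to_numpy()
        clade = tv > np.quantile(tv, 0.8)
        opt = tv[clade].mean()
        w = np.exp(-10 * (tv - opt) ** 2)
        p = np.full(60, 1 / 60)
        t = assemble_selective(p, 5000, w, 20, seed=3)
        share = t.counts[:, clade].sum() / t.counts.sum()
        assert share > 0.9

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError, match="zero"):
            assemble_selective(np.array([0.5, 0.5]), 100, np.zeros(2), 2)


@pytest.fixture(scope="module")
def bundle():
    cfg = SynthConfig(n_taxa=120, n_replicates=2, local_size_N=1000,
                      assembly_mode="mixed", seed=5)
    return cfg, simulate_dataset(cfg)


class TestSimulateDataset:

    def test_design_shape(self, bundle):
        cfg, (table, meta, tree, traits, truth) = bundle
        assert table.n_samples == 2 * 4 * 4 * 2  # cultivar x comp x stage x rep
        assert table.n_asvs == 120
        meta.validate_against(table)
        assert set(meta.frame["stage"]) == set(STAGES)

    def test_even_depth_by_construction(self, bundle):
        cfg, (table, *_rest) = bundle
        assert (table.sample_sums() == cfg.local_size_N).all()

    def test_truth_records_mixing(self, bundle):
        cfg, (table, meta, tree, traits, truth) = bundle
        nodule_samples = meta.frame.index[meta.frame.compartment == "nodule"]
        for s in nodule_samples:
            assert truth.source_proportions[s] == cfg.source_chain_mix["nodule"]

    def test_core_taxa_present_everywhere_upstream(self, bundle):
        cfg, (table, meta, tree, traits, truth) = bundle
        idx = [table.asv_ids.index(a) for a in truth.core_taxa]
        for comp in ("bulk_soil", "rhizosphere", "root"):
            rows = meta.frame.index[meta.frame.compartment == comp]
            sub = table.select_samples(list(rows))
            assert (sub.counts[:, idx] > 0).all()

    def test_traits_align_with_samples(self, bundle):
        cfg, (table, meta, tree, traits, truth) = bundle
        assert list(traits.frame.index) == table.sample_ids
        assert set(truth.trait_coefficients) == set(traits.frame.columns)

    def test_reproducible(self):
        cfg = SynthConfig(n_taxa=60, n_replicates=1, local_size_N=500, seed=8)
        t1, *_ = simulate_dataset(cfg)
        t2, *_ = simulate_dataset(cfg)
        assert np.array_equal(t1.counts, t2.counts)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            SynthConfig(source_chain_mix={"root": {"rhizosphere": 0.5,
                                                   "novel": 0.2}})
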
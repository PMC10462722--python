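"""Phylogenetic null-model inference of community assembly (beta-NTI).

The beta mean nearest taxon distance (betaMNTD) between two communities is
the abundance-weighted mean phylogenetic distance from each taxon to its
nearest relative in the other community. beta-NTI standardizes the observed
betaMNTD against a null distribution obtained by shuffling the tip labels
of the phylogeny (breaking the association between phylogenetic position
and abundance). |beta-NTI| >= 2 is read as deterministic assembly:
negative values indicate homogeneous selection (communities more
phylogenetically similar than expected), positive values variable
selection; |beta-NTI| < 2 is consistent with stochastic assembly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_data import AsvTable, cophenetic_matrix

__all__ = ["bmntd", "BetaNTI", "BetaNtiResult", "stochastic_fraction"]


def _weights(counts: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundance or 1/S over present taxa."""
    present = counts > 0
    if weighted:
        sums = counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return counts / sums
    richness = present.sum(axis=1, keepdims=True).astype(float)
    richness[richness == 0] = 1.0
    return present / richness


def _nearest_taxon_matrix(dist: np.ndarray, presence: np.ndarray) -> np.ndarray:
    """M[m, i] = distance from taxon i to its nearest taxon present in sample m.

    The diagonal of ``dist`` is zero, so taxa shared by both communities
    contribute zero nearest-taxon distance (self-match allowed).
    """
    n_samples = presence.shape[0]
    out = np.empty((n_samples, dist.shape[0]))
    for m in range(n_samples):
        out[m] = dist[:, presence[m]].min(axis=1)
    return out


def _bmntd_matrix(weights: np.ndarray, min_dist: np.ndarray) -> np.ndarray:
    g = weights @ min_dist.T  # g[k, m] = sum_i f_ki * min_{j in m} D(i, j)
    return 0.5 * (g + g.T)


def bmntd(table: AsvTable, tree: TreeNode, weighted: bool = True) -> pd.DataFrame:
    """Observed betaMNTD matrix over all sample pairs."""
    table = table.drop_empty_asvs()
    dist = cophenetic_matrix(tree, table.asv_ids)
    w = _weights(table.counts, weighted)
    m = _nearest_taxon_matrix(dist, table.counts > 0)
    mat = _bmntd_matrix(w, m)
    np.fill_diagonal(mat, 0.0)
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class BetaNtiResult:
    """beta-NTI fit: observed betaMNTD z-scored against the tip-shuffle null."""

    bnti: pd.DataFrame
    bmntd_obs: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    n_randomizations: int
    null_draws: np.ndarray | None = field(default=None, repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bnti.index)

    def pairwise(self) -> pd.DataFrame:
        """Long-format table of the upper-triangle pairs."""
        ids = self.sample_ids
        rows = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append({
                    "sample_i": ids[i], "sample_j": ids[j],
                    "bmntd": self.bmntd_obs.iat[i, j],
                    "null_mean": self.null_mean.iat[i, j],
                    "null_sd": self.null_sd.iat[i, j],
                    "bnti": self.bnti.iat[i, j],
                })
        return pd.DataFrame(rows)

    def stochastic_fraction(self, threshold: float = 2.0) -> float:
        return stochastic_fraction(self, threshold)

    def summary(self) -> pd.DataFrame:
        vals = _upper_triangle(self.bnti.to_numpy())
        finite = vals[np.isfinite(vals)]
        return pd.DataFrame({
            "n_pairs": [len(vals)],
            "n_finite": [len(finite)],
            "mean_bnti": [finite.mean() if len(finite) else np.nan],
            "stochastic_fraction": [self.stochastic_fraction()
                                    if len(finite) else np.nan],
            "n_randomizations": [self.n_randomizations],
        })


def _upper_triangle(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


class BetaNTI:
    """Null-model standardization of betaMNTD by tip-label shuffling.

    Parameters
    ----------
    table : AsvTable
        Rarefied count table; pairs are computed over all its samples, so
        pass one group (e.g. one compartment x cultivar cell) at a time
        when per-group panels are wanted.
    tree : skbio.TreeNode
        Rooted phylogeny covering every ASV column in the table.
    weighted : bool
        Abundance-weighted betaMNTD (default) or presence/absence.

    Notes
    -----
    The table's full column set — not just the taxa observed in these
    samples — defines the species pool over which tip labels are shuffled.
    Pass the metacommunity-wide table subset by *samples* (keeping all
    columns) so that the null can relocate clade-confined communities
    anywhere on the regional tree; shrinking the pool to the observed taxa
    would shuffle within the very clade selection produced and erase the
    signal.
    """

    def __init__(self, table: AsvTable, tree: TreeNode, weighted: bool = True):
        self.table = table
        self.weighted = weighted
        self._dist = cophenetic_matrix(tree, self.table.asv_ids)
        self._presence = self.table.counts > 0
        self._w = _weights(self.table.counts, weighted)

    def fit(self, n_rand: int = 999, seed: int | None = None,
            keep_null_draws: bool = False) -> BetaNtiResult:
        if n_rand < 99:
            warnings.warn(f"n_rand={n_rand} is low; 999 is the conventional "
                          "choice, 99 a reasonable floor")
        rng = np.random.default_rng(seed)
        ids = self.table.sample_ids
        n_taxa = self._dist.shape[0]

        m_obs = _nearest_taxon_matrix(self._dist, self._presence)
        obs = _bmntd_matrix(self._w, m_obs)

        nulls = np.empty((n_rand, len(ids), len(ids)))
        for r in range(n_rand):
            perm = rng.permutation(n_taxa)
            dist_perm = self._dist[np.ix_(perm, perm)]
            m_null = _nearest_taxon_matrix(dist_perm, self._presence)
            nulls[r] = _bmntd_matrix(self._w, m_null)

        null_mean = nulls.mean(axis=0)
        null_sd = nulls.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bnti = (obs - null_mean) / null_sd
        degenerate = null_sd == 0
        np.fill_diagonal(degenerate, False)
        if degenerate.any():
            warnings.warn(f"{int(degenerate.sum() // 2)} pair(s) with zero "
                          "null spread; beta-NTI set to NaN")
            bnti[degenerate] = np.nan
        np.fill_diagonal(bnti, 0.0)

        as_df = lambda a: pd.DataFrame(a, index=ids, columns=ids)
        return BetaNtiResult(
            bnti=as_df(bnti), bmntd_obs=as_df(obs),
            null_mean=as_df(null_mean), null_sd=as_df(null_sd),
            n_randomizations=n_rand,
            null_draws=nulls if keep_null_draws else None,
        )


def stochastic_fraction(result: BetaNtiResult, threshold: float = 2.0) -> float:
    """Share of finite sample pairs with |beta-NTI| below the threshold."""
    vals = _upper_triangle(result.bnti.to_numpy())
    finite = vals[np.isfinite(vals)]
    n_excluded = len(vals) - len(finite)
    if len(finite) == 0:
        raise ValueError("all beta-NTI pairs are NaN")
    if n_excluded:
        warnings.warn(f"{n_excluded} NaN pair(s) excluded from the "
                      "stochastic fraction")
    return float((np.abs(finite) < threshold).mean())
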
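"""Alpha/beta diversity, PERMANOVA, Mantel and hierarchical partitioning.

PERMANOVA is presented statsmodels-style: ``Permanova(dm, groups)`` is the
model, ``.fit()`` returns a :class:`PermanovaResult` carrying the pseudo-F,
R-squared and the permutation p-value. The one-factor form is used, applied
factor by factor, since each design factor is reported with its own
R-squared / p pair.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .core_data import AsvTable

__all__ = [
    "chao1",
    "beta_matrix",
    "Permanova",
    "PermanovaResult",
    "permanova",
    "mantel",
    "hier_partition",
    "HierPartResult",
]


# ----------------------------------------------------------------------
# Alpha diversity
# ----------------------------------------------------------------------

def chao1(counts: np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate for one sample's count vector.

    classic:        S_obs + F1^2 / (2 F2)
    bias-corrected: S_obs + F1 (F1 - 1) / (2 (F2 + 1))

    where F1 / F2 are the singleton / doubleton counts. The corrected form
    (default) is finite when no doubletons are observed.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    s_obs = int((counts > 0).sum())
    if s_obs == 0:
        warnings.warn("all-zero sample; Chao1 = 0")
        return 0.0
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2.0  # classic fallback when F2 = 0
    return s_obs + f1 * f1 / (2.0 * f2)


# ----------------------------------------------------------------------
# Beta diversity
# ----------------------------------------------------------------------

def beta_matrix(table: AsvTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample dissimilarity matrix.

    ``bray_curtis`` is abundance-weighted; ``jaccard_binary`` is computed on
    presence/absence (1 - intersection/union of the taxon sets).
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if metric == "bray_curtis":
        condensed = pdist(table.counts.astype(float), metric="braycurtis")
    elif metric == "jaccard_binary":
        condensed = pdist(table.counts > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------

@dataclass
class PermanovaResult:
    """One-factor PERMANOVA fit: Anderson's pseudo-F via label permutation."""

    factor: str
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int
    method: str = "sampled"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": [self.factor],
                "pseudo_F": [self.pseudo_F],
                "R2": [self.R2],
                "p_value": [self.p_value],
                "n_perm": [self.n_permutations],
                "method": [self.method],
            }
        )


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    levels = pd.unique(groups)
    return [np.flatnonzero(groups == g) for g in levels]


def _ss_within(d2: np.ndarray, idx_groups: list[np.ndarray]) -> float:
    ssw = 0.0
    for idx in idx_groups:
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ssw


def _pseudo_f(d2: np.ndarray, labels: np.ndarray):
    n = len(labels)
    idx_groups = _group_indices(labels)
    a = len(idx_groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, idx_groups)
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total
    return f, r2


class Permanova:
    """Permutational multivariate ANOVA on a distance matrix, one factor.

    Partitions the sum of squared distances among vs. within the levels of
    a single grouping factor; significance comes from permuting the sample
    labels. ``fit(method='exact')`` enumerates every permutation of the
    label vector, for small designs.
    """

    def __init__(self, dm: DistanceMatrix, groups, factor: str = "group"):
        self.dm = dm
        self.groups = np.asarray(groups)
        self.factor = factor
        if len(self.groups) != dm.shape[0]:
            raise ValueError("group labels do not match distance matrix size")
        levels, counts = np.unique(self.groups, return_counts=True)
        if len(levels) < 2:
            raise ValueError("need at least 2 groups")
        if counts.max() == len(self.groups):
            raise ValueError("one group absorbs all samples")
        self._d2 = np.asarray(dm.data, dtype=float) ** 2

    def fit(self, n_perm: int = 999, seed: int | None = None,
            method: str = "sampled") -> PermanovaResult:
        if n_perm < 1 and method == "sampled":
            raise ValueError("n_perm must be >= 1")
        labels = self.groups
        f_obs, r2 = _pseudo_f(self._d2, labels)
        n = len(labels)
        if method == "exact":
            count = 0
            total = 0
            for perm in itertools.permutations(range(n)):
                f_p, _ = _pseudo_f(self._d2, labels[list(perm)])
                count += f_p >= f_obs - 1e-12
                total += 1
            p = count / total
            n_used = total
        elif method == "sampled":
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                f_p, _ = _pseudo_f(self._d2, labels[perm])
                count += f_p >= f_obs - 1e-12
            p = (count + 1) / (n_perm + 1)
            n_used = n_perm
        else:
            raise ValueError(f"unknown method {method!r}")
        return PermanovaResult(
            factor=self.factor, pseudo_F=float(f_obs), R2=float(r2),
            p_value=float(p), n_permutations=n_used, n_samples=n,
            n_groups=len(np.unique(labels)), method=method,
        )


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None, factor: str = "group",
              method: str = "sampled") -> PermanovaResult:
    """Functional wrapper around :class:`Permanova`."""
    return Permanova(dm, groups, factor=factor).fit(n_perm=n_perm, seed=seed,
                                                    method=method)


# ----------------------------------------------------------------------
# Mantel test
# ----------------------------------------------------------------------

def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None, alternative: str = "two-sided"):
    """Mantel correlation between two distance matrices over the same samples.

    Pearson r over the upper triangle; the null permutes one matrix's
    sample labels. Degenerate (constant) matrices return NaN with a
    warning.
    """
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in size")
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    a = np.asarray(d1.data, float)
    b = np.asarray(d2.data, float)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    y = b[iu]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant distance matrix; Mantel r undefined")
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = b[np.ix_(perm, perm)][iu]
        r_p = float(np.corrcoef(x, yp)[0, 1])
        if alternative == "greater":
            count += r_p >= r_obs - 1e-12
        elif alternative == "less":
            count += r_p <= r_obs + 1e-12
        else:
            count += abs(r_p) >= abs(r_obs) - 1e-12
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)


# ----------------------------------------------------------------------
# Hierarchical variance partitioning (Chevan & Sutherland)
# ----------------------------------------------------------------------

@dataclass
class HierPartResult:
    """Independent contribution of each predictor to explained variance."""

    independent: pd.Series  # I_j per predictor, sums to full-model R2
    full_r2: float
    subset_r2: dict  # frozenset of predictor names -> R2

    def summary(self) -> pd.DataFrame:
        out = self.independent.to_frame("independent_R2")
        out["share_of_explained"] = out["independent_R2"] / self.full_r2 \
            if self.full_r2 > 0 else np.nan
        return out


def _dummy_code(factors: pd.DataFrame) -> dict[str, np.ndarray]:
    blocks = {}
    for col in factors.columns:
        d = pd.get_dummies(factors[col].astype(str), drop_first=True)
        blocks[col] = d.to_numpy(dtype=float)
    return blocks


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(len(y)), X]) if X.size else \
        np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    return 1.0 - (resid ** 2).sum() / sst


def hier_partition(response, factors: pd.DataFrame) -> HierPartResult:
    """Hierarchical partitioning of variance in a numeric response.

    Fits OLS models for every subset of the (dummy-coded) categorical
    predictors; the independent contribution of predictor j averages its
    marginal R-squared gain over all orderings. The contributions sum to
    the full-model R-squared exactly.
    """
    y = np.asarray(response, dtype=float)
    names = list(factors.columns)
    k = len(names)
    if k == 0 or k > 4:
        raise ValueError("between 1 and 4 predictors supported")
    for col in names:
        if factors[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than 2 levels")
    blocks = _dummy_code(factors)
    total_dim = sum(b.shape[1] for b in blocks.values())
    if len(y) <= total_dim:
        raise ValueError("more dummy dimensions than samples")

    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, k + 1):
        for subset in itertools.combinations(names, r):
            X = np.hstack([blocks[s] for s in subset])
            key = frozenset(subset)
            r2[key] = _ols_r2(y, X)
    full = frozenset(names)
    if k == len(names):
        X_full = np.hstack([blocks[s] for s in names])
        rank = np.linalg.matrix_rank(
            np.column_stack([np.ones(len(y)), X_full]))
        if rank < X_full.shape[1] + 1:
            raise ValueError("rank-deficient full model")

    indep = {}
    for j in names:
        others = [x for x in names if x != j]
        total = 0.0
        for r in range(0, k):
            for subset in itertools.combinations(others, r):
                s = frozenset(subset)
                weight = (math.factorial(r) * math.factorial(k - r - 1)
                          / math.factorial(k))
                total += weight * (r2[s | {j}] - r2[s])
        indep[j] = total
    series = pd.Series(indep, name="independent_R2")
    return HierPartResult(independent=series, full_r2=r2[full],
                          subset_r2={k_: v for k_, v in r2.items()})
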
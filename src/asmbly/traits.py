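"""Microbe-trait association: Spearman screen and permutation-tested
random-forest importance.

The screen correlates per-taxon relative abundances with each plant trait
(Spearman rank correlation with midrank ties), adjusts p-values by
Benjamini-Hochberg within each trait, and flags associations that are both
significant (p < 0.05) and strong (|rho| > 0.5). The forest step fits a
random-forest regressor per trait and scores each taxon by out-of-bag
permutation importance (mean decrease in accuracy); per-taxon significance
comes from refitting with the response permuted.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .core_data import AsvTable, TraitTable

__all__ = ["spearman_screen", "rf_importance"]


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for small n (full enumeration)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


def spearman_screen(table: AsvTable, traits: TraitTable,
                    method: str = "spearman",
                    p_cut: float = 0.05, rho_cut: float = 0.5) -> pd.DataFrame:
    """Correlation screen of taxa against traits, long format.

    Returns one row per (taxon, trait) with rho, p, BH q within trait and
    ``pass_filter`` = (p < p_cut and |rho| > rho_cut). For fewer than 10
    paired observations the p-value comes from exact permutation instead of
    the t-approximation. ``method='pearson'`` is available but the rank
    correlation is the primary screen.
    """
    rel = table.relative_abundance()
    common = [s for s in table.sample_ids if s in traits.frame.index]
    if len(common) < 4:
        raise ValueError("need at least 4 paired observations")
    idx = [table.sample_ids.index(s) for s in common]
    rel = rel[idx]
    tframe = traits.frame.loc[common]

    rows = []
    n = len(common)
    for trait_name in tframe.columns:
        y = tframe[trait_name].to_numpy(dtype=float)
        for j, asv in enumerate(table.asv_ids):
            x = rel[:, j]
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"constant vector for {asv}/{trait_name}; "
                              "rho undefined")
                rows.append({"asv_id": asv, "trait": trait_name,
                             "rho": np.nan, "p_value": np.nan})
                continue
            if method == "pearson":
                rho, p = stats.pearsonr(x, y)
            else:
                rho, p = stats.spearmanr(x, y)
                if n < 10:
                    p = _spearman_exact_p(x, y, rho)
            rows.append({"asv_id": asv, "trait": trait_name,
                         "rho": float(rho), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for trait_name, grp in out.groupby("trait"):
        ok = grp["p_value"].notna()
        if ok.any():
            q = multipletests(grp.loc[ok, "p_value"], method="fdr_bh")[1]
            out.loc[grp.index[ok], "q_value"] = q
    out["pass_filter"] = (out["p_value"] < p_cut) & (out["rho"].abs() > rho_cut)
    return out


def _oob_permutation_importance(forest: RandomForestRegressor,
                                X: np.ndarray, y: np.ndarray,
                                rng: np.random.Generator) -> np.ndarray:
    """Mean decrease in accuracy: rise in per-tree OOB MSE after permuting
    each predictor among that tree's out-of-bag samples."""
    n, p = X.shape
    importances = np.zeros(p)
    n_used = np.zeros(p)
    for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samples)
        if len(oob) < 2:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm_mse = np.mean((tree.predict(Xp) - yo) ** 2)
            importances[j] += perm_mse - base
            n_used[j] += 1
    n_used[n_used == 0] = 1
    return importances / n_used


def rf_importance(table: AsvTable, trait: pd.Series, n_trees: int = 500,
                  n_response_perms: int = 100, seed: int | None = None,
                  max_features: float | str = 1.0 / 3) -> pd.DataFrame:
    """Per-taxon random-forest importance with response-permutation p-values.

    Fits an ensemble regressor of ``n_trees`` bootstrap trees predicting
    the trait from relative abundances; importance is the out-of-bag
    permutation importance. The null refits the forest
    ``n_response_perms`` times with the response shuffled; p_j is the rank
    of the observed importance in that null (+1 correction).
    """
    common = [s for s in table.sample_ids if s in trait.index]
    if len(common) < 8:
        raise ValueError("need at least 8 samples")
    if table.n_asvs < 2:
        raise ValueError("need at least 2 predictor taxa")
    y = trait.loc[common].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant response")
    idx = [table.sample_ids.index(s) for s in common]
    X = table.relative_abundance()[idx]

    rng = np.random.default_rng(seed)

    def _fit_importance(y_fit: np.ndarray, rs: int) -> np.ndarray:
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features=max_features,
            bootstrap=True, random_state=rs, n_jobs=1)
        forest.fit(X, y_fit)
        return _oob_permutation_importance(forest, X, y_fit, rng)

    obs = _fit_importance(y, int(rng.integers(2**31)))
    exceed = np.zeros(table.n_asvs)
    for _ in range(n_response_perms):
        y_perm = rng.permutation(y)
        null_imp = _fit_importance(y_perm, int(rng.integers(2**31)))
        exceed += null_imp >= obs - 1e-15
    p = (exceed + 1) / (n_response_perms + 1)
    return pd.DataFrame({"rf_importance": obs, "rf_p": p},
                        index=table.asv_ids)
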
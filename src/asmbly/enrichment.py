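"""Enrichment decision rule on externally supplied differential statistics.

The differential model itself (negative-binomial GLM per taxon) is out of
scope here: this module takes its per-ASV outputs (log2 fold change and
raw p-value), applies Benjamini-Hochberg FDR adjustment and the decision
rule — enriched if log2FC > 2 and q < 0.05, depleted if log2FC < -2 and
q < 0.05 (symmetric rule), otherwise unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["call_enrichment", "naive_log2fc"]

LOG2FC_CUT = 2.0
Q_CUT = 0.05


def call_enrichment(stats: pd.DataFrame, log2fc_cut: float = LOG2FC_CUT,
                    q_cut: float = Q_CUT) -> pd.DataFrame:
    """Apply BH adjustment and the threshold rule to per-ASV statistics.

    ``stats`` needs columns ``log2fc`` and ``p_value`` (indexed by ASV id).
    Returns the input plus ``q_value`` and ``call``; inequalities are
    strict, so log2fc exactly at the cutoff is 'unchanged'.
    """
    required = {"log2fc", "p_value"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = stats.copy()
    if len(out) == 0:
        out["q_value"] = pd.Series(dtype=float)
        out["call"] = pd.Series(dtype=object)
        return out
    vals = out[["log2fc", "p_value"]].to_numpy(dtype=float)
    if not np.isfinite(vals[:, 0]).all():
        raise ValueError("non-finite log2fc")
    if ((vals[:, 1] < 0) | (vals[:, 1] > 1)).any():
        raise ValueError("p_value outside [0, 1]")
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    call = np.full(len(out), "unchanged", dtype=object)
    sig = out["q_value"].to_numpy() < q_cut
    call[(out["log2fc"].to_numpy() > log2fc_cut) & sig] = "enriched"
    call[(out["log2fc"].to_numpy() < -log2fc_cut) & sig] = "depleted"
    out["call"] = call
    return out


def summarize_calls(calls: pd.DataFrame) -> dict:
    n_enriched = int((calls["call"] == "enriched").sum())
    n_depleted = int((calls["call"] == "depleted").sum())
    return {
        "n_enriched": n_enriched,
        "n_depleted": n_depleted,
        "ratio": n_enriched / n_depleted if n_depleted else np.inf,
    }


def naive_log2fc(counts_a: np.ndarray, counts_b: np.ndarray,
                 pseudocount: float = 0.5) -> np.ndarray:
    """Synthetic-test helper: log2 ratio of mean relative abundances with a
    pseudocount. Deliberately NOT equivalent to a negative-binomial model;
    use only to exercise the decision rule on generated data."""
    a = np.asarray(counts_a, float) + pseudocount
    b = np.asarray(counts_b, float) + pseudocount
    pa = (a / a.sum(axis=1, keepdims=True)).mean(axis=0)
    pb = (b / b.sum(axis=1, keepdims=True)).mean(axis=0)
    return np.log2(pa / pb)
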
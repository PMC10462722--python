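"""Bayesian microbial source tracking by collapsed Gibbs sampling.

Each sink community is modelled as a mixture of the known source
environments plus an "Unknown" source whose taxon profile is latent. Every
sink read carries a latent source assignment z; the collapsed Gibbs
conditional combines how plausible the read's taxon is under each source
(Dirichlet-smoothed) with how many of the sink's other reads that source
currently claims:

    P(z_i = k | .) prop.to (n_{t_i,k} + alpha_k) / (n_{.,k} + alpha_k*T)
                         * (m_k^{-i} + beta) / (m_total - 1 + beta*K)

with alpha_k = alpha1 for known sources and alpha2 for the Unknown source,
whose taxon counts are the current read assignments themselves. The
reported proportions are posterior means over post-burn-in draws, averaged
over independent restarts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .core_data import AsvTable

__all__ = ["SourceTracker", "SourceProportions", "gibbs_source_track",
           "chain_report"]


@njit(cache=True)
def _gibbs_one_sink(read_taxa, src_counts, src_totals, alpha1, alpha2, beta,
                    n_burnin, n_draws, thin, uniforms):
    """Collapsed Gibbs for one sink. src_counts: K x T known-source counts.

    Source index K (one past the known sources) is the Unknown source.
    Returns draws of mixing proportions, (n_draws, K+1).
    """
    n_reads = read_taxa.shape[0]
    K = src_counts.shape[0]
    T = src_counts.shape[1]
    K_all = K + 1

    unk_taxon = np.zeros(T)
    env = np.zeros(K_all)
    z = np.empty(n_reads, np.int64)

    u_idx = 0
    # init: random assignment
    for i in range(n_reads):
        k = int(uniforms[u_idx] * K_all)
        if k == K_all:
            k = K_all - 1
        u_idx += 1
        z[i] = k
        env[k] += 1.0
        if k == K:
            unk_taxon[read_taxa[i]] += 1.0

    n_sweeps = n_burnin + n_draws * thin
    draws = np.zeros((n_draws, K_all))
    d = 0
    probs = np.empty(K_all)
    for sweep in range(n_sweeps):
        for i in range(n_reads):
            t = read_taxa[i]
            k_old = z[i]
            env[k_old] -= 1.0
            if k_old == K:
                unk_taxon[t] -= 1.0
            tot = 0.0
            for k in range(K):
                like = (src_counts[k, t] + alpha1) / \
                       (src_totals[k] + alpha1 * T)
                prior = (env[k] + beta) / (n_reads - 1.0 + beta * K_all)
                probs[k] = like * prior
                tot += probs[k]
            like = (unk_taxon[t] + alpha2) / (env[K] + alpha2 * T)
            prior = (env[K] + beta) / (n_reads - 1.0 + beta * K_all)
            probs[K] = like * prior
            tot += probs[K]

            u = uniforms[u_idx] * tot
            u_idx += 1
            acc = 0.0
            k_new = K_all - 1
            for k in range(K_all):
                acc += probs[k]
                if u <= acc:
                    k_new = k
                    break
            z[i] = k_new
            env[k_new] += 1.0
            if k_new == K:
                unk_taxon[t] += 1.0
        if sweep >= n_burnin and (sweep - n_burnin) % thin == thin - 1:
            for k in range(K_all):
                draws[d, k] = env[k] / n_reads
            d += 1
    return draws


@dataclass
class SourceProportions:
    """Posterior source-mixing proportions per sink sample."""

    mean: pd.DataFrame  # sinks x (sources + Unknown)
    sd: pd.DataFrame
    settings: dict

    @property
    def sources(self) -> list[str]:
        return list(self.mean.columns)

    def summary(self) -> pd.DataFrame:
        return self.mean

    def to_long(self) -> pd.DataFrame:
        long = self.mean.reset_index(names="sink").melt(
            id_vars="sink", var_name="source", value_name="proportion")
        sd_long = self.sd.reset_index(names="sink").melt(
            id_vars="sink", var_name="source", value_name="sd")
        return long.merge(sd_long, on=["sink", "source"])


class SourceTracker:
    """SourceTracker-style Gibbs mixture model over source environments.

    Source samples are aggregated per environment by summing counts. Sink
    samples are (optionally) rarefied to ``rarefaction_depth`` reads before
    the per-read Gibbs sweep, for tractability.
    """

    def __init__(self, sources: AsvTable, source_env: dict[str, list[str]] | pd.Series,
                 alpha1: float = 0.001, alpha2: float = 0.1, beta: float = 10.0):
        if isinstance(source_env, pd.Series):
            env_map: dict[str, list[str]] = {}
            for sid, env in source_env.items():
                env_map.setdefault(str(env), []).append(str(sid))
        else:
            env_map = {k: list(v) for k, v in source_env.items()}
        self.env_names = list(env_map)
        if not self.env_names:
            raise ValueError("no source environments given")
        self.asv_ids = list(sources.asv_ids)
        mat = np.zeros((len(self.env_names), sources.n_asvs))
        for k, env in enumerate(self.env_names):
            sub = sources.select_samples(env_map[env])
            mat[k] = sub.counts.sum(axis=0)
        self.src_counts = mat
        self.alpha1, self.alpha2, self.beta = alpha1, alpha2, beta

    def fit(self, sinks: AsvTable, n_burnin: int = 100, n_draws: int = 100,
            thin: int = 10, restarts: int = 2, seed: int | None = None,
            rarefaction_depth: int | None = 1000) -> SourceProportions:
        if sinks.asv_ids != self.asv_ids:
            raise ValueError("sink and source tables must share the ASV axis")
        depths = sinks.sample_sums()
        if (depths == 0).any():
            bad = [s for s, t in zip(sinks.sample_ids, depths) if t == 0]
            raise ValueError(f"zero-depth sink sample(s): {bad}")
        rng = np.random.default_rng(seed)
        cols = self.env_names + ["Unknown"]
        means = np.zeros((sinks.n_samples, len(cols)))
        sds = np.zeros_like(means)
        src_totals = self.src_counts.sum(axis=1)
        for s in range(sinks.n_samples):
            row = sinks.counts[s]
            if rarefaction_depth and row.sum() > rarefaction_depth:
                row = rng.multivariate_hypergeometric(row, rarefaction_depth)
            read_taxa = np.repeat(
                np.arange(len(row)), row).astype(np.int64)
            all_draws = []
            for _ in range(max(restarts, 1)):
                n_sweeps = n_burnin + n_draws * thin
                n_u = len(read_taxa) * (n_sweeps + 1)
                uniforms = rng.random(n_u)
                order = rng.permutation(len(read_taxa))
                draws = _gibbs_one_sink(
                    read_taxa[order], self.src_counts, src_totals,
                    self.alpha1, self.alpha2, self.beta,
                    n_burnin, n_draws, thin, uniforms)
                all_draws.append(draws)
            stacked = np.vstack(all_draws)
            means[s] = stacked.mean(axis=0)
            sds[s] = stacked.std(axis=0)
        mean_df = pd.DataFrame(means, index=sinks.sample_ids, columns=cols)
        sd_df = pd.DataFrame(sds, index=sinks.sample_ids, columns=cols)
        return SourceProportions(
            mean=mean_df, sd=sd_df,
            settings={"alpha1": self.alpha1, "alpha2": self.alpha2,
                      "beta": self.beta, "n_burnin": n_burnin,
                      "n_draws": n_draws, "thin": thin,
                      "restarts": restarts, "seed": seed,
                      "rarefaction_depth": rarefaction_depth})


def gibbs_source_track(sinks: AsvTable, sources: AsvTable, source_env,
                       alpha1: float = 0.001, alpha2: float = 0.1,
                       beta: float = 10.0, n_burnin: int = 100,
                       n_draws: int = 100, thin: int = 10, restarts: int = 2,
                       seed: int | None = None,
                       rarefaction_depth: int | None = 1000) -> SourceProportions:
    """Functional wrapper around :class:`SourceTracker`."""
    model = SourceTracker(sources, source_env, alpha1=alpha1, alpha2=alpha2,
                          beta=beta)
    return model.fit(sinks, n_burnin=n_burnin, n_draws=n_draws, thin=thin,
                     restarts=restarts, seed=seed,
                     rarefaction_depth=rarefaction_depth)


def chain_report(props: SourceProportions, compartments: pd.Series) -> pd.DataFrame:
    """Mean attribution per sink-compartment x source pair, long format."""
    mean = props.mean.copy()
    mean["compartment"] = compartments.reindex(mean.index)
    grouped = mean.groupby("compartment").mean()
    return grouped.reset_index().melt(
        id_vars="compartment", var_name="source",
        value_name="mean_proportion")
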
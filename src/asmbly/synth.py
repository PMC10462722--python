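"""Synthetic community generator with known assembly processes.

Emulates a 2-cultivar x 4-stage x 4-compartment root-microbiome design
(bulk soil -> rhizosphere -> root endosphere -> nodule) in which every
quantity the downstream analyses estimate is known by construction:

* the metacommunity relative abundances and the migration rate ``m`` of
  the Sloan neutral model (local communities are drawn from its stationary
  Beta law),
* phylogenetically conserved habitat preferences (traits evolved by
  Brownian motion on a simulated birth-death tree) driving Gaussian
  stabilizing selection, so that phylogenetic null models (beta-NTI) have
  a real signal to detect,
* per-compartment source-mixing proportions along the soil-to-nodule
  chain (ground truth for Bayesian source tracking),
* designated core taxa present across all stages, and plant traits that
  are linear functions of designated taxa plus Gaussian noise.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_data import AsvTable, SampleMetadata, TraitTable, COMPARTMENTS, CULTIVARS

STAGES = ("V2", "R2", "R5", "R8")  # vegetative to full-maturity stages

__all__ = [
    "STAGES",
    "SynthConfig",
    "SynthTruth",
    "simulate_tree",
    "brownian_traits",
    "simulate_metacommunity",
    "assemble_neutral",
    "assemble_selective",
    "selection_weights",
    "adaptive_selection_strength",
    "calibration_dataset",
    "simulate_dataset",
]


# ----------------------------------------------------------------------
# Configuration & truth containers
# ----------------------------------------------------------------------

def _default_chain() -> dict:
    return {
        "rhizosphere": {"bulk_soil": 0.7, "novel": 0.3},
        "root": {"rhizosphere": 0.8, "novel": 0.2},
        "nodule": {"root": 0.8, "novel": 0.2},
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic design.

    The defaults emulate the study layout: 2 cultivars (normal- and
    super-nodulating) x 4 developmental stages x 4 compartments with 3
    replicates, ~300 taxa, 2000 reads per sample and migration m = 0.25
    (N*m = 500).
    """

    n_taxa: int = 300
    n_replicates: int = 3
    compartments: tuple = COMPARTMENTS
    stages: tuple = STAGES
    cultivars: tuple = CULTIVARS
    mu_log: float = 0.0
    sigma_log: float = 1.5
    assembly_mode: str = "neutral"  # neutral | homogeneous_selection | variable_selection | mixed
    migration_m: float = 0.25
    local_size_N: int = 2000
    selection_strength: float = 5.0
    selection_migration_m: float = 0.005  # drift inside selective compartments
    optimum_quantile: float = 0.9  # trait quantile targeted by selection
    adaptive_clade_mass: float | None = None  # normalize s to this favored mass
    trait_sigma_bm: float = 1.0
    stage_effect_sigma: float = 0.0
    source_chain_mix: dict = field(default_factory=_default_chain)
    n_core_taxa: int = 10
    core_boost: float = 10.0  # expected reads per core taxon per sample floor
    trait_links: list = field(default_factory=list)
    trait_noise_sd: float = 0.5
    seed: int = 0

    @classmethod
    def mixed_study(cls, seed: int = 0, **overrides) -> "SynthConfig":
        """The default mixed-assembly study: neutral soil and rhizosphere,
        selection inside the plant (root, nodule), stage-structured
        background taxa, planted cores and trait links — sized so every
        downstream stage has detectable signal (1000 taxa, 5000 reads,
        5 replicates per design cell)."""
        params = dict(
            n_taxa=1000, n_replicates=5, assembly_mode="mixed",
            local_size_N=5000, migration_m=0.25, sigma_log=0.5,
            selection_migration_m=0.005, adaptive_clade_mass=0.10,
            optimum_quantile=0.9, stage_effect_sigma=1.0,
            core_boost=25.0, seed=seed,
        )
        params.update(overrides)
        return cls(**params)

    def __post_init__(self) -> None:
        if not (0 < self.migration_m <= 1):
            raise ValueError("migration_m must be in (0, 1]")
        if self.local_size_N < 1:
            raise ValueError("local_size_N must be >= 1")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        for comp, mix in self.source_chain_mix.items():
            tot = sum(mix.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"source mix for {comp} sums to {tot}, not 1")
        modes = {"neutral", "homogeneous_selection", "variable_selection", "mixed"}
        if self.assembly_mode not in modes:
            raise ValueError(f"assembly_mode must be one of {sorted(modes)}")
        if not self.trait_links:
            # default: each trait driven by a pair of core taxa
            self.trait_links = [
                ([0, 1], "plant_biomass", 2.0),
                ([2, 3], "aboveground_N", 2.0),
                ([4, 5], "underground_C", -2.0),
                ([6, 7], "nodule_number", 2.0),
            ]


@dataclass
class SynthTruth:
    """Everything needed to score downstream estimates without re-simulation."""

    metacommunity_p: np.ndarray
    migration_m: float
    local_size_N: int
    habitat_traits: np.ndarray  # per-taxon Brownian trait values
    optima: dict  # (cultivar, compartment, stage) -> env optimum (or None)
    source_proportions: dict  # sample_id -> {source name: fraction}
    core_taxa: list[str]
    trait_coefficients: dict  # trait name -> {taxon id: beta}
    pools: dict  # (cultivar, compartment, stage) -> sampling pool used

    def to_jsonable(self) -> dict:
        return {
            "migration_m": self.migration_m,
            "local_size_N": self.local_size_N,
            "Nm": self.migration_m * self.local_size_N,
            "core_taxa": self.core_taxa,
            "source_proportions": self.source_proportions,
            "trait_coefficients": self.trait_coefficients,
            "metacommunity_p": self.metacommunity_p.tolist(),
        }


# ----------------------------------------------------------------------
# Tree + trait simulation
# ----------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth_rate: float = 1.0, death_rate: float = 0.0,
                  seed: int | None = None) -> TreeNode:
    """Simulate a birth-death tree with tips labelled ASV_1..ASV_n."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = _random.Random(seed)
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_taxa, rng=rng,
    )
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"ASV_{i}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read([newick])
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            node.length = 1e-8
    return tree


def brownian_traits(tree: TreeNode, sigma_bm: float = 1.0,
                    seed: int | None = None) -> pd.Series:
    """Evolve a continuous trait by Brownian motion along the tree.

    Returns per-tip values standardized to zero mean / unit variance so
    that selection-strength parameters are on a fixed scale.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        step = rng.normal(0.0, sigma_bm * np.sqrt(max(node.length, 1e-12)))
        values[id(node)] = parent_val + step
    tips = list(tree.tips())
    raw = np.array([values[id(t)] for t in tips])
    sd = raw.std()
    if sd > 0:
        raw = (raw - raw.mean()) / sd
    return pd.Series(raw, index=[t.name for t in tips])


# ----------------------------------------------------------------------
# Community assembly kernels
# ----------------------------------------------------------------------

def simulate_metacommunity(n_taxa: int, mu_log: float = 0.0, sigma_log: float = 1.5,
                           seed: int | None = None) -> np.ndarray:
    """Lognormal species-abundance distribution, normalized to sum to 1."""
    rng = np.random.default_rng(seed)
    if sigma_log == 0:
        return np.full(n_taxa, 1.0 / n_taxa)
    raw = rng.lognormal(mu_log, sigma_log, size=n_taxa)
    return raw / raw.sum()


def assemble_neutral(p: np.ndarray, N: int, m: float, n_samples: int,
                     seed: int | None = None,
                     sample_ids: Sequence[str] | None = None,
                     asv_ids: Sequence[str] | None = None) -> AsvTable:
    """Draw local communities from the Sloan stationary neutral law.

    Per taxon, the local relative abundance is Beta(N*m*p_i, N*m*(1-p_i))
    (independent approximation, renormalized), then N reads are drawn
    multinomially. The Beta dispersion is what the neutral-model fit
    estimates back as N*m.
    """
    if not (0 < m <= 1):
        raise ValueError("m must be in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.asarray(p, dtype=float)
    counts = np.zeros((n_samples, len(p)), dtype=np.int64)
    Nm = N * m
    a = Nm * p
    b = Nm * (1.0 - p)
    for s in range(n_samples):
        if np.allclose(p.max(), 1.0):  # degenerate single-taxon metacommunity
            freqs = p.copy()
        else:
            freqs = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
            tot = freqs.sum()
            freqs = freqs / tot if tot > 0 else p
        counts[s] = rng.multinomial(N, freqs)
    sample_ids = sample_ids or [f"S{i+1}" for i in range(n_samples)]
    asv_ids = asv_ids or [f"ASV_{i+1}" for i in range(len(p))]
    return AsvTable(counts, list(sample_ids), list(asv_ids))


def selection_weights(traits: np.ndarray, optimum: float,
                      strength: float) -> np.ndarray:
    """Gaussian stabilizing-selection fitness: w = exp(-s * (trait-opt)^2)."""
    return np.exp(-strength * (np.asarray(traits, float) - optimum) ** 2)


def adaptive_selection_strength(traits: np.ndarray, optimum: float,
                                clade_mass: float = 0.10) -> float:
    """Selection strength s such that the mean Gaussian fitness over the
    pool equals ``clade_mass``.

    Fixing the favored fraction of the species pool (rather than s itself)
    makes the effective clade size comparable across simulated trees,
    which otherwise varies widely with where the Brownian trait extreme
    happens to fall; bisection on log(s).
    """
    tv = np.asarray(traits, float)
    lo, hi = 1e-1, 5e2
    for _ in range(60):
        mid = float(np.sqrt(lo * hi))
        if selection_weights(tv, optimum, mid).mean() > clade_mass:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def assemble_selective(p: np.ndarray, N: int, fitness_weights: np.ndarray,
                       n_samples: int, seed: int | None = None,
                       migration_m: float | None = None,
                       sample_ids: Sequence[str] | None = None,
                       asv_ids: Sequence[str] | None = None) -> AsvTable:
    """Selection-weighted community draws: probabilities prop.to p_i * w_i.

    With ``migration_m=None`` each sample is a plain multinomial on the
    weighted pool (pure selection, no drift): all samples then share the
    same expected composition. Passing a migration rate layers neutral
    drift on top of selection — each sample's frequencies are drawn from
    Beta(N*m*p'_i, N*m*(1-p'_i)) around the weighted pool p' before the
    multinomial — producing taxon turnover *within* the favored clade,
    the regime where phylogenetic nulls can actually see homogeneous
    selection (identical communities carry no betaMNTD signal because
    shared taxa sit at zero nearest-taxon distance under any tip shuffle).
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(fitness_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("fitness weights must be nonnegative")
    probs = p * w
    tot = probs.sum()
    if tot <= 0:
        raise ValueError("all effective sampling weights are zero")
    probs = probs / tot
    rng = np.random.default_rng(seed)
    if migration_m is None:
        counts = rng.multinomial(N, probs, size=n_samples)
    else:
        if not (0 < migration_m <= 1):
            raise ValueError("migration_m must be in (0, 1]")
        nm = N * migration_m
        a = np.maximum(nm * probs, 1e-12)
        b = np.maximum(nm * (1.0 - probs), 1e-12)
        counts = np.zeros((n_samples, len(p)), dtype=np.int64)
        for s in range(n_samples):
            x = rng.beta(a, b)
            x = x / x.sum()
            counts[s] = rng.multinomial(N, x)
    sample_ids = sample_ids or [f"S{i+1}" for i in range(n_samples)]
    asv_ids = asv_ids or [f"ASV_{i+1}" for i in range(len(p))]
    return AsvTable(counts.astype(np.int64), list(sample_ids), list(asv_ids))


def calibration_dataset(regime: str, seed: int, n_samples: int = 20):
    """One replicate of the beta-NTI calibration conditions.

    ``regime='neutral'``: 150 taxa, 2000 reads, migration m = 0.25 — the
    stationary Sloan draw with no selection; mean pairwise beta-NTI should
    stay inside (-2, 2).

    ``regime='homogeneous_selection'``: a 1500-taxon regional pool with a
    fairly even abundance structure on a high-extinction birth-death tree
    (deep clade contrast), stabilizing selection toward the 0.9 quantile
    of the Brownian habitat trait (an extreme value, hence a coherent
    clade), with strength normalized so the favored clade holds ~10% of
    the pool, shared by every sample; strong drift (m = 0.005) makes
    communities turn over within the favored clade. Mean pairwise
    beta-NTI should fall below -2.

    Returns ``(table, tree)``.
    """
    rng = np.random.default_rng(seed)
    if regime == "neutral":
        n_taxa, N = 150, 2000
        tree = simulate_tree(n_taxa, seed=int(rng.integers(2**31)))
        p = simulate_metacommunity(n_taxa, 0.0, 1.5,
                                   seed=int(rng.integers(2**31)))
        table = assemble_neutral(p, N, 0.25, n_samples,
                                 seed=int(rng.integers(2**31)))
    elif regime == "homogeneous_selection":
        n_taxa, N = 1500, 6000
        tree = simulate_tree(n_taxa, birth_rate=1.0, death_rate=0.7,
                             seed=int(rng.integers(2**31)))
        traits = brownian_traits(tree, 1.0, seed=int(rng.integers(2**31)))
        asv_ids = [f"ASV_{i+1}" for i in range(n_taxa)]
        trait_vec = traits.reindex(asv_ids).to_numpy()
        p = simulate_metacommunity(n_taxa, 0.0, 0.5,
                                   seed=int(rng.integers(2**31)))
        opt = float(np.quantile(trait_vec, 0.9))
        w = selection_weights(trait_vec, opt,
                              adaptive_selection_strength(trait_vec, opt))
        table = assemble_selective(p, N, w, n_samples,
                                   seed=int(rng.integers(2**31)),
                                   migration_m=0.005, asv_ids=asv_ids)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return table, tree


# ----------------------------------------------------------------------
# Full-design simulation
# ----------------------------------------------------------------------

def _compartment_is_selective(mode: str, compartment: str) -> bool:
    if mode == "neutral":
        return False
    if mode in ("homogeneous_selection", "variable_selection"):
        return True
    # mixed: selection inside the plant, neutral outside
    return compartment in ("root", "nodule")


def simulate_dataset(config: SynthConfig):
    """Generate the full design with recorded ground truth.

    Returns ``(table, metadata, tree, traits, truth)``. Compartments are
    generated in chain order within each (cultivar, stage) cell: bulk soil
    samples come from the metacommunity; each downstream compartment's
    sampling pool is a mixture of the realized upstream mean profile and a
    compartment-specific novel pool, per ``source_chain_mix`` — the mixture
    is the ground truth for source tracking.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_taxa
    asv_ids = [f"ASV_{i+1}" for i in range(n)]

    death = 0.7 if cfg.assembly_mode != "neutral" else 0.0
    tree = simulate_tree(n, birth_rate=1.0, death_rate=death, seed=cfg.seed)
    habitat_traits = brownian_traits(tree, cfg.trait_sigma_bm,
                                     seed=int(rng.integers(2**31)))
    trait_vec = habitat_traits.reindex(asv_ids).to_numpy()

    p_meta = simulate_metacommunity(n, cfg.mu_log, cfg.sigma_log,
                                    seed=int(rng.integers(2**31)))

    core_idx = np.asarray(
        rng.choice(n, size=min(cfg.n_core_taxa, n), replace=False))
    core_taxa = [asv_ids[i] for i in core_idx]
    # guarantee detection of core taxa everywhere upstream of the nodule
    floor = cfg.core_boost / cfg.local_size_N
    p_core = p_meta.copy()
    p_core[core_idx] = np.maximum(p_core[core_idx], floor)
    p_core = p_core / p_core.sum()

    # per-(taxon, stage) habitat multipliers for non-core taxa
    stage_mult = np.ones((len(cfg.stages), n))
    if cfg.stage_effect_sigma > 0:
        stage_mult = rng.lognormal(0.0, cfg.stage_effect_sigma,
                                   size=(len(cfg.stages), n))
        stage_mult[:, core_idx] = 1.0

    # novel pools per (cultivar, compartment): lognormal over all taxa,
    # independent of the metacommunity ranking, so they are well separated
    novel_pools = {}
    for cv in cfg.cultivars:
        for comp in cfg.compartments[1:]:
            raw = rng.lognormal(cfg.mu_log, max(cfg.sigma_log, 1.0), size=n)
            pool = raw / raw.sum()
            pool[core_idx] = np.maximum(pool[core_idx], floor)
            novel_pools[(cv, comp)] = pool / pool.sum()

    optima: dict = {}
    pools: dict = {}
    source_props: dict = {}
    counts_rows = []
    meta_rows = []
    sample_ids = []

    sel_scale = {"NNS": 1.0, "SNS": 1.2}

    # selection targets an extreme trait quantile: under Brownian evolution
    # the trait extreme is clade-coherent, so selection is phylogenetically
    # conserved and visible to nearest-taxon null models
    plant_optimum = float(np.quantile(trait_vec, cfg.optimum_quantile))

    for cv in cfg.cultivars:
        # root and nodule share the plant-interior optimum (homogeneous
        # selection along the endosphere chain)
        comp_opt = {comp: plant_optimum for comp in cfg.compartments}
        upstream_profile: dict[str, dict[str, np.ndarray]] = {}
        for comp in cfg.compartments:
            upstream_profile[comp] = {}
            for si, stage in enumerate(cfg.stages):
                # Stage structure enters only through the rhizosphere's
                # novel (compartment-specific) pool: bulk soil is a stable
                # neutral habitat, and applying stage multipliers after
                # mixing would silently change the source-mixing truth.
                if comp == "bulk_soil":
                    pool = p_core.copy()
                    mix = None
                else:
                    mix = cfg.source_chain_mix[comp]
                    novel_part = novel_pools[(cv, comp)]
                    if comp == "rhizosphere" and cfg.stage_effect_sigma > 0:
                        novel_part = novel_part * stage_mult[si]
                        novel_part = novel_part / novel_part.sum()
                    pool = np.zeros(n)
                    for src, frac in mix.items():
                        if src == "novel":
                            pool += frac * novel_part
                        else:
                            pool += frac * upstream_profile[src][stage]
                    pool = pool / pool.sum()

                selective = _compartment_is_selective(cfg.assembly_mode, comp)
                if selective:
                    if cfg.assembly_mode == "variable_selection":
                        opt = float(np.quantile(trait_vec,
                                                rng.uniform(0.05, 0.95)))
                    else:
                        opt = comp_opt[comp]
                    optima[(cv, comp, stage)] = opt
                    if cfg.adaptive_clade_mass is not None:
                        base_s = adaptive_selection_strength(
                            trait_vec, opt, cfg.adaptive_clade_mass)
                    else:
                        base_s = cfg.selection_strength
                    s = base_s * sel_scale.get(cv, 1.0)
                    w = selection_weights(trait_vec, opt, s)
                else:
                    optima[(cv, comp, stage)] = None
                    w = np.ones(n)

                ids = [f"{cv}_{comp}_{stage}_r{r+1}"
                       for r in range(cfg.n_replicates)]
                sub_seed = int(rng.integers(2**31))
                if selective:
                    sub = assemble_selective(
                        pool, cfg.local_size_N, w, cfg.n_replicates,
                        seed=sub_seed, migration_m=cfg.selection_migration_m,
                        sample_ids=ids, asv_ids=asv_ids)
                elif comp == "bulk_soil":
                    # Sloan drift around the metacommunity: the habitat
                    # whose N*m truth the neutral-model fit is scored on
                    sub = assemble_neutral(
                        pool, cfg.local_size_N, cfg.migration_m,
                        cfg.n_replicates, seed=sub_seed,
                        sample_ids=ids, asv_ids=asv_ids)
                else:
                    # downstream neutral compartments: multinomial reads
                    # straight from the mixed pool, so the source-mixing
                    # proportions stay recoverable (extra Beta drift would
                    # shift attribution mass to the Unknown source)
                    sub = assemble_selective(
                        pool, cfg.local_size_N, np.ones(n),
                        cfg.n_replicates, seed=sub_seed,
                        sample_ids=ids, asv_ids=asv_ids)

                # core taxa are regulated populations: near-constant
                # abundance in every sample (3% CV), the generator's model
                # of niche-stabilized generalists — detectably more even
                # across stages than multinomial drift
                core_target = np.maximum(pool[core_idx] * cfg.local_size_N,
                                         cfg.core_boost)
                jitter = rng.lognormal(0.0, 0.005,
                                       size=(cfg.n_replicates, len(core_idx)))
                sub.counts[:, core_idx] = np.rint(core_target * jitter)
                # re-level every sample to exactly N reads (absorb the
                # residual in its most abundant non-core taxon) so the
                # simulated design has even depth by construction
                non_core = np.setdiff1d(np.arange(n), core_idx)
                for r in range(cfg.n_replicates):
                    resid = cfg.local_size_N - int(sub.counts[r].sum())
                    j = non_core[np.argmax(sub.counts[r, non_core])]
                    sub.counts[r, j] = max(sub.counts[r, j] + resid, 0)

                rel = sub.relative_abundance()
                upstream_profile[comp][stage] = rel.mean(axis=0)
                pools[(cv, comp, stage)] = pool
                for r, sid in enumerate(ids):
                    counts_rows.append(sub.counts[r])
                    sample_ids.append(sid)
                    meta_rows.append({"compartment": comp, "stage": stage,
                                      "cultivar": cv, "replicate": r + 1})
                    if mix is not None:
                        source_props[sid] = dict(mix)

    table = AsvTable(np.vstack(counts_rows), sample_ids, asv_ids)
    metadata = SampleMetadata(pd.DataFrame(meta_rows, index=sample_ids))

    # plant traits: linear in designated taxa's relative abundances + noise
    rel = table.relative_abundance()
    trait_cols = {}
    coeffs: dict = {}
    for link_idx, trait_name, beta in cfg.trait_links:
        taxa = [core_taxa[i] if isinstance(i, int) and i < len(core_taxa)
                else str(i) for i in link_idx]
        cols = [asv_ids.index(t) for t in taxa]
        z = rel[:, cols]
        sd = z.std(axis=0)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=0)) / sd
        signal = beta * z.mean(axis=1)
        noise = rng.normal(0, cfg.trait_noise_sd, size=table.n_samples)
        trait_cols[trait_name] = signal + noise
        coeffs[trait_name] = {t: beta for t in taxa}
    traits = TraitTable(pd.DataFrame(trait_cols, index=sample_ids))

    truth = SynthTruth(
        metacommunity_p=p_core, migration_m=cfg.migration_m,
        local_size_N=cfg.local_size_N, habitat_traits=trait_vec,
        optima=optima, source_proportions=source_props,
        core_taxa=core_taxa, trait_coefficients=coeffs, pools=pools,
    )
    return table, metadata, tree, traits, truth
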
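"""End-to-end orchestration: load -> rarefy -> diversity -> beta-NTI ->
neutral model -> niche/core -> source tracking -> traits, from one config.

Every stage writes TSV/JSON results into the output directory and records
its parameters and derived seed in ``manifest.json``. Per-stage seeds are
a pure function of the global seed and the stage name, so any stage can be
re-run in isolation and reproduce its part of a full run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import BetaNTI
from .core_data import (AsvTable, SampleMetadata, TraitTable, default_depth,
                        rarefy, read_asv_table, read_metadata, read_traits,
                        read_tree, write_asv_table)
from .diversity import Permanova, beta_matrix, chao1, hier_partition
from .ncm import SloanNCM
from .niche import NicheClassifier, core_generalists
from .sourcetrack import SourceTracker, chain_report
from .synth import SynthConfig, simulate_dataset
from .traits import rf_importance, spearman_screen

__all__ = ["RunConfig", "run_all", "stage_seed", "write_simulation",
           "evaluate_against_truth"]

CHAIN_DEFAULT = {
    "rhizosphere": ["bulk_soil"],
    "root": ["rhizosphere", "bulk_soil"],
    "nodule": ["root", "rhizosphere"],
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    traits: str | None = None
    out_dir: str = "asmbly_out"
    seed: int = 0
    depth: int | None = None  # None -> floor(0.95 * min depth)
    permanova_factors: tuple = ("compartment", "stage", "cultivar")
    permanova_perms: int = 999
    bnti_group: tuple = ("compartment", "cultivar")
    bnti_rand: int = 999
    ncm_group: tuple = ("compartment", "cultivar")
    niche_within: str = "compartment"
    niche_classes: str = "stage"
    niche_perms: int = 1000
    chain_map: dict = field(default_factory=lambda: dict(CHAIN_DEFAULT))
    sourcetrack_depth: int = 1000
    rf_trees: int = 500
    rf_perms: int = 100
    stages: tuple = ("rarefy", "diversity", "bnti", "ncm", "niche",
                     "sourcetrack", "traits")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("permanova_factors", "bnti_group", "ncm_group", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def write_simulation(config: SynthConfig, out_dir: str | Path) -> dict:
    """Run the generator and write table/metadata/tree/traits/truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, metadata, tree, traits, truth = simulate_dataset(config)
    write_asv_table(table, out / "table.tsv")
    metadata.frame.to_csv(out / "metadata.tsv", sep="\t")
    tree.write(str(out / "tree.nwk"))
    traits.frame.to_csv(out / "traits.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)
    return {"table": str(out / "table.tsv"),
            "metadata": str(out / "metadata.tsv"),
            "tree": str(out / "tree.nwk"),
            "traits": str(out / "traits.tsv"),
            "truth": str(out / "truth.json")}


def _group_iter(metadata: SampleMetadata, sample_ids, factors):
    meta = metadata.loc(sample_ids)
    if not factors:
        yield ("all",), list(sample_ids)
        return
    for key, grp in meta.groupby(list(factors), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        yield key, list(grp.index)


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of result objects."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}}
    results: dict = {}

    if config.table is None:
        raise ValueError("config.table is required")
    table = read_asv_table(config.table)
    metadata = read_metadata(config.metadata) if config.metadata else None
    if metadata is not None:
        metadata.validate_against(table)
    tree = read_tree(config.tree) if config.tree else None
    traits = read_traits(config.traits) if config.traits else None

    # ---- rarefaction ---------------------------------------------------
    if "rarefy" in config.stages:
        depth = config.depth or default_depth(table)
        table = rarefy(table, depth, seed=stage_seed(config.seed, "rarefy"))
        write_asv_table(table, out / "table_rarefied.tsv")
        manifest["stages"]["rarefy"] = {"depth": depth}
        results["depth"] = depth

    sample_ids = table.sample_ids

    # ---- diversity -----------------------------------------------------
    if "diversity" in config.stages:
        seed = stage_seed(config.seed, "diversity")
        alpha = pd.Series({s: chao1(table.counts[i])
                           for i, s in enumerate(sample_ids)}, name="chao1")
        alpha.to_csv(out / "alpha_chao1.tsv", sep="\t")
        perm_rows = []
        dms = {}
        for metric in ("bray_curtis", "jaccard_binary"):
            dm = beta_matrix(table, metric)
            dms[metric] = dm
            if metadata is not None:
                for factor in config.permanova_factors:
                    groups = metadata.factor(factor, sample_ids)
                    res = Permanova(dm, groups, factor=factor).fit(
                        n_perm=config.permanova_perms, seed=seed)
                    row = res.summary().iloc[0].to_dict()
                    row["metric"] = metric
                    perm_rows.append(row)
        if perm_rows:
            pd.DataFrame(perm_rows).to_csv(out / "permanova.tsv", sep="\t",
                                           index=False)
            results["permanova"] = pd.DataFrame(perm_rows)
        if metadata is not None:
            factors = metadata.loc(sample_ids)[list(config.permanova_factors)]
            try:
                vpa = hier_partition(alpha.to_numpy(), factors)
                vpa.summary().to_csv(out / "vpa_chao1.tsv", sep="\t")
                results["vpa"] = vpa
            except ValueError as err:
                warnings.warn(f"VPA skipped: {err}")
        results["alpha"] = alpha
        results["beta"] = dms
        manifest["stages"]["diversity"] = {
            "perms": config.permanova_perms, "seed": seed}

    # ---- beta-NTI ------------------------------------------------------
    if "bnti" in config.stages:
        if tree is None:
            raise FileNotFoundError("beta-NTI requested but no tree supplied")
        seed = stage_seed(config.seed, "bnti")
        rows = []
        group_summaries = []
        for key, ids in _group_iter(metadata, sample_ids, config.bnti_group):
            if len(ids) < 3:
                continue
            sub = table.select_samples(ids)
            res = BetaNTI(sub, tree).fit(n_rand=config.bnti_rand, seed=seed)
            long = res.pairwise()
            long.insert(0, "group", "|".join(map(str, key)))
            rows.append(long)
            summ = res.summary()
            summ.insert(0, "group", "|".join(map(str, key)))
            group_summaries.append(summ)
        bnti_long = pd.concat(rows, ignore_index=True)
        bnti_long.to_csv(out / "bnti.tsv", sep="\t", index=False)
        bnti_summary = pd.concat(group_summaries, ignore_index=True)
        bnti_summary.to_csv(out / "bnti_summary.tsv", sep="\t", index=False)
        results["bnti"] = bnti_long
        results["bnti_summary"] = bnti_summary
        manifest["stages"]["bnti"] = {"rand": config.bnti_rand, "seed": seed}

    # ---- neutral model -------------------------------------------------
    if "ncm" in config.stages:
        rows = []
        fits = {}
        for key, ids in _group_iter(metadata, sample_ids, config.ncm_group):
            sub = table.select_samples(ids)
            if sub.n_samples < 5:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = SloanNCM(sub).fit()
            fits["|".join(map(str, key))] = fit
            row = fit.summary().iloc[0].to_dict()
            row["group"] = "|".join(map(str, key))
            rows.append(row)
        ncm_df = pd.DataFrame(rows)
        ncm_df.to_csv(out / "ncm.tsv", sep="\t", index=False)
        results["ncm"] = fits
        results["ncm_summary"] = ncm_df
        manifest["stages"]["ncm"] = {"group": list(config.ncm_group)}

    # ---- niche & core --------------------------------------------------
    if "niche" in config.stages and metadata is not None:
        seed = stage_seed(config.seed, "niche")
        meta = metadata.loc(sample_ids)
        class_rows = []
        per_cell: dict = {}
        for cv in sorted(meta["cultivar"].unique()):
            for comp in sorted(meta[config.niche_within].unique()):
                mask = (meta["cultivar"] == cv) & \
                       (meta[config.niche_within] == comp)
                ids = list(meta.index[mask])
                if len(ids) < 4:
                    continue
                sub = table.select_samples(ids).drop_empty_asvs()
                labels = meta.loc[ids, config.niche_classes].to_numpy()
                if len(pd.unique(labels)) < 2:
                    continue
                cls = NicheClassifier(sub, labels).fit(
                    n_perm=config.niche_perms, seed=seed)
                per_cell[(cv, comp)] = cls
                frame = cls.frame.reset_index(names="asv_id")
                frame.insert(0, "cultivar", cv)
                frame.insert(1, config.niche_within, comp)
                class_rows.append(frame)
        niche_df = pd.concat(class_rows, ignore_index=True)
        niche_df.to_csv(out / "niche.tsv", sep="\t", index=False)
        cores = {}
        for cv in sorted(meta["cultivar"].unique()):
            cls_by_comp = {comp: cls for (c, comp), cls in per_cell.items()
                           if c == cv}
            try:
                cores[cv] = sorted(core_generalists(
                    cls_by_comp, table, metadata, cv))
            except ValueError as err:
                warnings.warn(f"core set for {cv} skipped: {err}")
        shared = sorted(set.intersection(*(set(v) for v in cores.values()))) \
            if cores else []
        with open(out / "core_generalists.json", "w") as fh:
            json.dump({"per_cultivar": cores, "shared": shared}, fh, indent=1)
        results["niche"] = per_cell
        results["core"] = {"per_cultivar": cores, "shared": shared}
        manifest["stages"]["niche"] = {"perms": config.niche_perms,
                                       "seed": seed}

    # ---- source tracking -----------------------------------------------
    if "sourcetrack" in config.stages and metadata is not None:
        seed = stage_seed(config.seed, "sourcetrack")
        meta = metadata.loc(sample_ids)
        reports = []
        per_sink = []
        for sink_comp, source_comps in config.chain_map.items():
            sink_ids = list(meta.index[meta["compartment"] == sink_comp])
            if not sink_ids:
                continue
            env_map = {}
            for sc in source_comps:
                ids = list(meta.index[meta["compartment"] == sc])
                if ids:
                    env_map[sc] = ids
            if not env_map:
                continue
            sinks = table.select_samples(sink_ids)
            model = SourceTracker(table, env_map)
            props = model.fit(sinks, seed=seed,
                              rarefaction_depth=config.sourcetrack_depth)
            long = props.to_long()
            long.insert(0, "sink_compartment", sink_comp)
            per_sink.append(long)
            rep = chain_report(props, meta["compartment"])
            rep.insert(0, "sink_compartment", sink_comp)
            reports.append(rep)
        if per_sink:
            pd.concat(per_sink, ignore_index=True).to_csv(
                out / "sourcetrack.tsv", sep="\t", index=False)
            report = pd.concat(reports, ignore_index=True)
            report.to_csv(out / "sourcetrack_report.tsv", sep="\t",
                          index=False)
            results["sourcetrack"] = report
        manifest["stages"]["sourcetrack"] = {"seed": seed,
                                             "map": config.chain_map}

    # ---- traits --------------------------------------------------------
    if "traits" in config.stages and traits is not None:
        seed = stage_seed(config.seed, "traits")
        core_ids = None
        if "core" in results:
            union = sorted(set().union(
                *(set(v) for v in results["core"]["per_cultivar"].values())))
            core_ids = union or None
        assoc_table = table.select_asvs(core_ids) if core_ids else table
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            screen = spearman_screen(assoc_table, traits)
        screen.to_csv(out / "trait_spearman.tsv", sep="\t", index=False)
        rf_rows = []
        for trait_name in traits.frame.columns:
            imp = rf_importance(assoc_table, traits.frame[trait_name],
                                n_trees=config.rf_trees,
                                n_response_perms=config.rf_perms, seed=seed)
            imp = imp.reset_index(names="asv_id")
            imp.insert(0, "trait", trait_name)
            rf_rows.append(imp)
        rf_df = pd.concat(rf_rows, ignore_index=True)
        rf_df.to_csv(out / "trait_rf.tsv", sep="\t", index=False)
        results["trait_screen"] = screen
        results["trait_rf"] = rf_df
        manifest["stages"]["traits"] = {"trees": config.rf_trees,
                                        "perms": config.rf_perms,
                                        "seed": seed}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results


NEUTRAL_COMPARTMENTS = ("bulk_soil", "rhizosphere")
SELECTIVE_COMPARTMENTS = ("root", "nodule")


def evaluate_against_truth(results: dict, truth: dict,
                           metadata: SampleMetadata) -> dict:
    """Score a pipeline run against the generator's recorded ground truth.

    Produces, for a mixed-assembly simulation: neutral-model N*m recovery
    in the drift-assembled compartments, pooled beta-NTI means for the
    neutral vs. selection-assembled compartments, source-proportion
    recovery on the neutral chain link (mixing truth is only identifiable
    upstream of selection, which re-weights the mixed pool), and planted
    core recall/precision.
    """
    report: dict = {}

    # --- neutral-model recovery -------------------------------------
    # scored on bulk soil, the compartment assembled from a single stable
    # metacommunity; the rhizosphere's pool varies with stage, which the
    # one-pool Sloan model does not describe
    true_nm = truth["Nm"]
    fitted = []
    for group, fit in results.get("ncm", {}).items():
        comp = group.split("|")[0]
        if comp == "bulk_soil":
            fitted.append(fit.Nm)
    if fitted:
        med = float(np.median(fitted))
        report["ncm"] = {
            "true_Nm": true_nm, "median_fitted_Nm": med,
            "relative_error": (med - true_nm) / true_nm,
            "fitted_per_group": fitted,
        }

    # --- beta-NTI regime separation ----------------------------------
    bnti = results.get("bnti")
    if bnti is not None:
        vals = bnti.dropna(subset=["bnti"]).copy()
        vals["compartment"] = vals["group"].str.split("|").str[0]
        pooled = {}
        for label, comps in (("neutral", NEUTRAL_COMPARTMENTS),
                             ("selective", SELECTIVE_COMPARTMENTS)):
            sub = vals[vals["compartment"].isin(comps)]["bnti"]
            if len(sub):
                pooled[label] = {
                    "mean_bnti": float(sub.mean()),
                    "stochastic_fraction": float((sub.abs() < 2).mean()),
                    "n_pairs": int(len(sub)),
                }
        report["bnti"] = pooled

    # --- source-proportion recovery ----------------------------------
    st = results.get("sourcetrack")
    if st is not None and truth.get("source_proportions"):
        first = next(iter(truth["source_proportions"].values()))
        comp_truth = {}
        meta = metadata.frame
        for sid, mix in truth["source_proportions"].items():
            comp = meta.loc[sid, "compartment"]
            comp_truth.setdefault(comp, mix)
        recov = {}
        for comp, mix in comp_truth.items():
            sub = st[st["sink_compartment"] == comp]
            est = {}
            for src, frac in mix.items():
                col = "Unknown" if src == "novel" else src
                got = sub[sub["source"] == col]["mean_proportion"]
                if len(got):
                    est[src] = {"true": frac, "estimated": float(got.iloc[0]),
                                "abs_error": abs(float(got.iloc[0]) - frac)}
            recov[comp] = est
        report["sourcetrack"] = recov

    # --- core recall / precision -------------------------------------
    core = results.get("core")
    if core is not None and truth.get("core_taxa"):
        true_core = set(truth["core_taxa"])
        per_cv = {}
        for cv, found in core["per_cultivar"].items():
            found = set(found)
            per_cv[cv] = {
                "recall": len(found & true_core) / len(true_core),
                "precision": (len(found & true_core) / len(found)
                              if found else 1.0),
                "n_found": len(found),
            }
        report["core"] = per_cv
    return report
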
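"""Levins niche breadth, generalist/specialist calls, core microbiome.

Niche breadth of taxon j over H habitat classes (here the four plant
developmental stages within one microhabitat) is the Levins index
B_j = 1 / sum_h P_jh^2, where P_jh is the share of taxon j's summed reads
falling in class h. B ranges from 1 (confined to one class, a specialist)
to H (spread evenly, a generalist). Significance comes from a permutation
null that reshuffles whole samples across habitat classes: a taxon is a
generalist if its observed B exceeds the null's 97.5% quantile, a
specialist if it falls below the 2.5% quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import AsvTable, SampleMetadata

__all__ = ["levins_b", "NicheClassifier", "NicheClassification",
           "classify_niche", "core_generalists"]


def levins_b(proportions) -> float:
    """Levins niche-breadth index B = 1 / sum(P_h^2) for one taxon."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    tot = p.sum()
    if tot == 0:
        raise ValueError("all-zero proportion vector")
    p = p / tot
    return float(1.0 / np.square(p).sum())


def _levins_all(class_sums: np.ndarray) -> np.ndarray:
    """Vectorized Levins B for every taxon from an H x T class-sum matrix."""
    tot = class_sums.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = tot ** 2 / np.square(class_sums).sum(axis=0)
    return b


@dataclass
class NicheClassification:
    """Per-ASV niche-breadth classification within one microhabitat."""

    frame: pd.DataFrame  # B_obs, null_lo, null_hi, label, occupancy
    n_permutations: int
    habitat_classes: list[str]

    @property
    def generalists(self) -> list[str]:
        return list(self.frame.index[self.frame["label"] == "generalist"])

    @property
    def specialists(self) -> list[str]:
        return list(self.frame.index[self.frame["label"] == "specialist"])

    def summary(self) -> pd.Series:
        return self.frame["label"].value_counts()


class NicheClassifier:
    """Permutation-null generalist/specialist classification.

    Two null models are available. The default, ``null='independence'``,
    randomizes the count matrix holding taxon totals and class read depths
    fixed — per taxon this reduces to a multinomial reallocation of its
    reads over habitat classes (the margin-preserving matrix randomization
    of the spec.gen lineage). A generalist is a taxon spread across
    classes *more evenly than multinomial resampling of itself*, i.e. a
    regulated population; a specialist is more concentrated than chance.

    ``null='sample_shuffle'`` instead permutes whole samples across
    classes (preserving per-sample composition). Note that this null can
    never call a taxon whose counts are exchangeable across samples a
    generalist — the observed B is itself a draw from that null — so it
    is mainly useful for testing class-structured restriction
    (specialists).
    """

    def __init__(self, table: AsvTable, habitat_labels):
        self.table = table
        self.labels = np.asarray(habitat_labels)
        if len(self.labels) != table.n_samples:
            raise ValueError("habitat labels do not match sample count")
        self.classes = list(pd.unique(self.labels))
        if len(self.classes) < 2:
            raise ValueError("need at least 2 habitat classes")
        counts = np.array([(self.labels == c).sum() for c in self.classes])
        if (counts == 0).any():
            raise ValueError("habitat class with zero samples")
        # S x H one-hot design
        self._onehot = np.stack(
            [(self.labels == c).astype(float) for c in self.classes])

    def fit(self, n_perm: int = 1000, seed: int | None = None,
            alpha: float = 0.05,
            null: str = "independence") -> NicheClassification:
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is low; 1000 is conventional")
        counts = self.table.counts.astype(float)
        obs_sums = self._onehot @ counts  # H x T
        present = obs_sums.sum(axis=0) > 0
        if not present.all():
            warnings.warn(f"excluding {int((~present).sum())} all-zero taxa")
        b_obs = _levins_all(obs_sums)

        rng = np.random.default_rng(seed)
        n = self.table.n_samples
        n_taxa = self.table.n_asvs
        nulls = np.empty((n_perm, n_taxa))
        if null == "independence":
            class_share = obs_sums.sum(axis=1) / counts.sum()
            totals = obs_sums.sum(axis=0).astype(np.int64)
            for j in range(n_taxa):
                if totals[j] == 0:
                    nulls[:, j] = np.nan
                    continue
                draw = rng.multinomial(totals[j], class_share, size=n_perm)
                nulls[:, j] = _levins_all(draw.T)
        elif null == "sample_shuffle":
            for r in range(n_perm):
                perm = rng.permutation(n)
                nulls[r] = _levins_all(self._onehot[:, perm] @ counts)
        else:
            raise ValueError(f"unknown null {null!r}")
        lo = np.nanquantile(nulls, alpha / 2, axis=0)
        hi = np.nanquantile(nulls, 1 - alpha / 2, axis=0)

        label = np.full(self.table.n_asvs, "non_significant", dtype=object)
        label[b_obs > hi] = "generalist"
        label[b_obs < lo] = "specialist"
        label[~present] = "excluded"
        occupancy = (obs_sums > 0).sum(axis=0)

        frame = pd.DataFrame({
            "B_obs": b_obs, "null_lo": lo, "null_hi": hi,
            "label": label, "occupancy": occupancy,
        }, index=self.table.asv_ids)
        frame = frame[present]
        return NicheClassification(frame=frame, n_permutations=n_perm,
                                   habitat_classes=[str(c) for c in self.classes])


def classify_niche(table: AsvTable, habitat_labels, n_perm: int = 1000,
                   seed: int | None = None) -> NicheClassification:
    """Functional wrapper around :class:`NicheClassifier`."""
    return NicheClassifier(table, habitat_labels).fit(n_perm=n_perm, seed=seed)


def core_generalists(
    classifications: dict,
    table: AsvTable,
    metadata: SampleMetadata,
    cultivar: str,
    compartments: tuple = ("bulk_soil", "rhizosphere", "root"),
    stage_col: str = "stage",
) -> set[str]:
    """Core generalist microbes for one cultivar.

    A taxon qualifies if, in every one of the given microhabitats (bulk
    soil, rhizosphere and root endosphere — nodules are excluded), it is
    (a) classified as a generalist there and (b) detected (count > 0 in at
    least one replicate) at every developmental stage. The result is the
    intersection across the three microhabitats.
    """
    meta = metadata.frame
    core: set[str] | None = None
    for comp in compartments:
        if comp not in classifications:
            raise ValueError(f"missing classification for {comp!r}")
        gen = set(classifications[comp].generalists)
        mask = (meta["compartment"] == comp) & (meta["cultivar"] == cultivar)
        samp = [s for s in table.sample_ids if s in meta.index[mask]]
        stages = pd.unique(meta.loc[samp, stage_col])
        if len(stages) == 0:
            raise ValueError(f"no samples for {cultivar} x {comp}")
        sub = table.select_samples(samp)
        stage_labels = meta.loc[samp, stage_col].to_numpy()
        detected_everywhere = np.ones(sub.n_asvs, dtype=bool)
        for st in stages:
            rows = sub.counts[stage_labels == st]
            if rows.size == 0:
                raise ValueError(f"empty design cell: {cultivar} x {comp} x {st}")
            detected_everywhere &= rows.sum(axis=0) > 0
        present = {a for a, d in zip(sub.asv_ids, detected_everywhere) if d}
        qualified = gen & present
        core = qualified if core is None else core & qualified
    return core if core is not None else set()
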
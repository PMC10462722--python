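"""Core domain containers and I/O for amplicon community analysis.

The universal input is an ASV (amplicon sequence variant) count table of
samples x taxa, accompanied by a rooted phylogeny over the ASVs, a sample
metadata table describing the experimental design (root compartment,
developmental stage, cultivar, replicate) and an optional plant-trait
table. Everything downstream (diversity, null models, neutral-model fits,
source tracking) consumes these containers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

COMPARTMENTS = ("bulk_soil", "rhizosphere", "root", "nodule")
CULTIVARS = ("NNS", "SNS")

__all__ = [
    "AsvTable",
    "SampleMetadata",
    "TraitTable",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "read_traits",
    "read_tree",
    "cophenetic_matrix",
    "rarefy",
    "default_depth",
    "COMPARTMENTS",
    "CULTIVARS",
]


@dataclass
class AsvTable:
    """A samples x ASVs matrix of nonnegative integer read counts.

    Parameters
    ----------
    counts : ndarray of shape (n_samples, n_asvs)
        Nonnegative integer read counts, sample-major.
    sample_ids, asv_ids : sequences of unique strings
        Row and column labels.
    """

    counts: np.ndarray
    sample_ids: list[str]
    asv_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x ASVs)")
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        for name, ids in (("sample", self.sample_ids), ("ASV", self.asv_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {name} ids: {sorted(dupes)}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            bad = np.argwhere(~np.isclose(self.counts, rounded, atol=1e-9))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"non-integer count {self.counts[i, j]!r} at sample "
                    f"{self.sample_ids[i]!r}, ASV {self.asv_ids[j]!r}"
                )
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"ASV {self.asv_ids[j]!r}"
            )

    # -- basic views ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Counts normalized per sample; zero-depth rows stay zero."""
        sums = self.sample_sums().astype(float)
        sums[sums == 0] = 1.0
        return self.counts / sums[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    # -- subsetting -------------------------------------------------------

    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AsvTable(self.counts[idx], list(sample_ids), list(self.asv_ids))

    def select_asvs(self, asv_ids: Sequence[str]) -> "AsvTable":
        idx = [self.asv_ids.index(a) for a in asv_ids]
        return AsvTable(self.counts[:, idx], list(self.sample_ids), list(asv_ids))

    def drop_empty_asvs(self) -> "AsvTable":
        keep = self.counts.sum(axis=0) > 0
        return AsvTable(
            self.counts[:, keep],
            list(self.sample_ids),
            [a for a, k in zip(self.asv_ids, keep) if k],
        )


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


@dataclass
class SampleMetadata:
    """Per-sample design factors: compartment, stage, cultivar, replicate."""

    frame: pd.DataFrame

    REQUIRED = ("compartment", "stage", "cultivar", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        bad_comp = set(self.frame["compartment"]) - set(COMPARTMENTS)
        if bad_comp:
            raise ValueError(f"unknown compartment values: {sorted(bad_comp)}")
        bad_cv = set(self.frame["cultivar"]) - set(CULTIVARS)
        if bad_cv:
            raise ValueError(f"unknown cultivar values: {sorted(bad_cv)}")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")

    def validate_against(self, table: AsvTable) -> None:
        missing = set(table.sample_ids) - set(self.frame.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def loc(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        return self.frame.loc[list(sample_ids)]

    def factor(self, name: str, sample_ids: Sequence[str]) -> np.ndarray:
        return self.frame.loc[list(sample_ids), name].to_numpy()


@dataclass
class TraitTable:
    """Per-sample numeric plant traits (biomass, N/C content, nodule number)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        nonnum = self.frame.select_dtypes(exclude="number").columns.tolist()
        if nonnum:
            raise ValueError(f"non-numeric trait columns: {nonnum}")
        if not np.isfinite(self.frame.to_numpy(dtype=float)).all():
            raise ValueError("trait table contains non-finite values")


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

def read_asv_table(path: str | Path, format: str = "tsv", transpose: bool = False,
                   drop_empty_samples: bool = True) -> AsvTable:
    """Read an ASV count table from TSV or BIOM 1.0 (JSON).

    TSV layout: header row of ASV ids, first column sample ids (or the
    transpose with ``transpose=True``). Zero-total samples are dropped with
    a warning rather than an error.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if transpose:
            df = df.T
        table = AsvTable(df.to_numpy(), list(df.index.astype(str)),
                         list(df.columns.astype(str)))
    elif format == "biom":
        table = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")
    if drop_empty_samples:
        sums = table.sample_sums()
        if (sums == 0).any():
            dropped = [s for s, t in zip(table.sample_ids, sums) if t == 0]
            warnings.warn(f"dropping zero-total samples: {dropped}")
            keep = [s for s, t in zip(table.sample_ids, sums) if t > 0]
            table = table.select_samples(keep)
    return table


def _read_biom_json(path: Path) -> AsvTable:
    """Minimal BIOM 1.0 JSON reader (rows = observations/ASVs)."""
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"])
    return AsvTable(mat.T, sample_ids, obs_ids)


def write_asv_table(table: AsvTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        table.to_dataframe().to_csv(path, sep="\t")
    elif format == "biom":
        rows = [{"id": a, "metadata": None} for a in table.asv_ids]
        cols = [{"id": s, "metadata": None} for s in table.sample_ids]
        obs = table.counts.T
        data = [[int(i), int(j), int(obs[i, j])]
                for i, j in zip(*np.nonzero(obs))]
        doc = {
            "id": None, "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table", "generated_by": "asmbly",
            "date": "", "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [table.n_asvs, table.n_samples],
            "rows": rows, "columns": cols, "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(df)


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def cophenetic_matrix(tree: TreeNode, asv_ids: Sequence[str]) -> np.ndarray:
    """Patristic (cophenetic) distance matrix over the given tips.

    Raises if any requested ASV is absent from the tree: phylogenetic
    stages require full tip coverage.
    """
    tips = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise KeyError(f"ASVs missing from the phylogeny: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    dm = tree.tip_tip_distances(endpoints=list(asv_ids))
    return np.asarray(dm.filter(list(asv_ids)).data, dtype=float)


# ----------------------------------------------------------------------
# Depth normalization
# ----------------------------------------------------------------------

def default_depth(table: AsvTable) -> int:
    """Rarefaction depth: floor of 95% of the lowest sample depth.

    The conservative reading of "95th percentile of the lowest sampling
    depth": it retains every sample while discounting 5% of the shallowest
    library.
    """
    if table.n_samples == 0:
        raise ValueError("empty table")
    return int(np.floor(0.95 * table.sample_sums().min()))


def rarefy(table: AsvTable, depth: int, seed: int | None = None) -> AsvTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Reproducible for a fixed seed (one child RNG stream per sample).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        warnings.warn(f"dropping samples below depth {depth}: {dropped}")
    out = np.zeros((int(keep.sum()), table.n_asvs), dtype=np.int64)
    kept_ids = []
    row_out = 0
    for i in range(table.n_samples):
        if not keep[i]:
            continue
        row = table.counts[i]
        total = sums[i]
        if total == depth:
            out[row_out] = row
        else:
            # multivariate hypergeometric = uniform subsample w/o replacement
            out[row_out] = rng.multivariate_hypergeometric(row, depth)
        kept_ids.append(table.sample_ids[i])
        row_out += 1
    return AsvTable(out, kept_ids, list(table.asv_ids))
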
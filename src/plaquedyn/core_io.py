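"""Readers, writers and alignment for community tables, trees and sample metadata.

The pipeline's in-memory currency is a taxa-by-sample abundance table
(:class:`CommunityTable`), a rooted phylogeny with branch lengths
(:class:`skbio.TreeNode`) whose tips name the taxa, and a per-sample metadata
frame (subject, timepoint label, hours since scaling, optional reconstruction
stage).  Tables travel as plain TSV — either a vanilla ``taxon\\tS1\\tS2...``
layout or the BIOM-style TSV dialect whose header line starts with
``#OTU ID`` — and trees as newick.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("plaquedyn")

__all__ = [
    "FormatError",
    "AlignmentError",
    "DegenerateSampleError",
    "CommunityTable",
    "Dataset",
    "TIMEPOINT_HOURS",
    "BASELINE_LABEL",
    "BASELINE_HOURS",
    "stage_of_hours",
    "read_table",
    "write_table",
    "to_relative",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "align_dataset",
]


class FormatError(ValueError):
    """A file violates the expected tabular format (duplicates, negatives...)."""


class AlignmentError(ValueError):
    """Table, tree and metadata cannot be reconciled into one dataset."""


class DegenerateSampleError(ValueError):
    """A sample carries no signal (all-zero column)."""


#: hours since scaling for the study's canonical post-perturbation labels
TIMEPOINT_HOURS: dict[str, float] = {
    "0h": 0.0,
    "1h": 1.0,
    "4h": 4.0,
    "7h": 7.0,
    "1d": 24.0,
    "3d": 72.0,
    "7d": 168.0,
    "14d": 336.0,
    "1m": 720.0,
    "3m": 2160.0,
    "1y": 8760.0,
}
BASELINE_LABEL = "baseline"
#: the pre-scaling sample is coded with a negative offset so "hours >= 0" means post-perturbation
BASELINE_HOURS = -1.0


def stage_of_hours(hours: float) -> str:
    """Reconstruction stage of a timepoint given its offset in hours.

    Early covers the first seven hours post-scaling, middle runs through the
    first week (1 d, 3 d, 1 w), late is everything from two weeks on.  The
    pre-scaling baseline is its own category.
    """
    if hours < 0:
        return "baseline"
    if hours <= 7:
        return "early"
    if hours <= 168:
        return "middle"
    return "late"


REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "timepoint", "hours")


@dataclass
class CommunityTable:
    """Taxa-by-sample abundance matrix.

    ``data`` holds taxa as rows and samples as columns; values are either raw
    counts or relative abundances (``is_relative``).  Identifiers must be
    unique and values non-negative.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("non-numeric values in community table")
        if (vals < 0).any():
            raise FormatError("negative values in community table")
        if self.is_relative:
            sums = vals.sum(axis=0)
            if np.abs(sums - 1.0).max() > 1e-8:
                raise FormatError("is_relative set but sample columns do not sum to 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, taxa=None, samples=None) -> "CommunityTable":
        df = self.data
        if taxa is not None:
            df = df.loc[list(taxa)]
        if samples is not None:
            df = df[list(samples)]
        return CommunityTable(df, is_relative=False if taxa is not None else self.is_relative)


@dataclass
class Dataset:
    """Mutually aligned table / tree / metadata triple."""

    table: CommunityTable
    tree: TreeNode
    metadata: pd.DataFrame
    dropped_taxa: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)


def _autodetect_relative(values: np.ndarray) -> bool:
    sums = values.sum(axis=0)
    return bool(np.all(np.abs(sums - 1.0) <= 1e-6))


def read_table(path, dialect: str = "tsv") -> CommunityTable:
    """Read a taxa-by-sample TSV abundance table.

    ``dialect="biom-tsv"`` accepts the classic BIOM text export: an optional
    ``# Constructed from biom file`` comment followed by a header line that
    starts with ``#OTU ID``.  Integral values are kept as integers.
    """
    if dialect not in ("tsv", "biom-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    if dialect == "biom-tsv":
        lines = text.splitlines()
        kept = []
        for line in lines:
            if line.startswith("#OTU ID"):
                kept.append(line.lstrip("#").strip())
            elif line.startswith("#"):
                continue  # comment line
            else:
                kept.append(line)
        text = "\n".join(kept)
    df = pd.read_csv(StringIO(text), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    table = CommunityTable(df)  # validates duplicates / negatives
    vals = df.to_numpy()
    if np.issubdtype(vals.dtype, np.number) and np.all(np.mod(vals, 1) == 0):
        df = df.astype(np.int64)
        table = CommunityTable(df)
    table.is_relative = _autodetect_relative(vals.astype(float))
    return table


def write_table(table: CommunityTable, path, dialect: str = "tsv") -> None:
    if dialect not in ("tsv", "biom-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if dialect == "tsv":
        table.data.to_csv(path, sep="\t", index_label="taxon")
    else:
        with open(path, "w") as fh:
            fh.write("# Constructed from biom file\n")
            header = "#OTU ID\t" + "\t".join(map(str, table.samples))
            fh.write(header + "\n")
            table.data.to_csv(fh, sep="\t", header=False)


def to_relative(table: CommunityTable) -> CommunityTable:
    """Normalize each sample column to sum to one (idempotent)."""
    vals = table.values
    sums = vals.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = [table.samples[i] for i in zero]
        raise DegenerateSampleError(f"all-zero sample column(s): {bad}")
    rel = pd.DataFrame(vals / sums, index=table.data.index, columns=table.data.columns)
    return CommunityTable(rel, is_relative=True)


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str, "timepoint": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise FormatError(f"metadata missing required column(s): {missing}")
    if md["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    md["hours"] = md["hours"].astype(float)
    if "stage" not in md.columns:
        md["stage"] = [stage_of_hours(h) for h in md["hours"]]
    return md


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate tip labels in tree")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def align_dataset(
    table: CommunityTable,
    tree: TreeNode,
    metadata: pd.DataFrame,
    max_dropped_frac: float = 0.10,
) -> Dataset:
    """Restrict table, tree and metadata to their common identifiers.

    Taxa absent from the tree are dropped (they have no branch placement, so
    phylogenetic metrics are undefined for them); an :class:`AlignmentError`
    is raised when more than ``max_dropped_frac`` of the table's taxa would be
    lost, or when either intersection is empty.  Idempotent.
    """
    tip_names = {t.name for t in tree.tips()}
    taxa_keep = [t for t in table.taxa if t in tip_names]
    dropped_taxa = [t for t in table.taxa if t not in tip_names]
    if not taxa_keep:
        raise AlignmentError("no table taxon matches a tree tip")
    frac = len(dropped_taxa) / len(table.taxa)
    if frac > max_dropped_frac:
        raise AlignmentError(
            f"{len(dropped_taxa)}/{len(table.taxa)} taxa absent from tree "
            f"({frac:.0%} > {max_dropped_frac:.0%} allowed)"
        )
    if dropped_taxa:
        logger.warning("dropping %d taxa absent from tree: %s", len(dropped_taxa), dropped_taxa)

    md_samples = list(metadata["sample_id"])
    samples_keep = [s for s in table.samples if s in set(md_samples)]
    dropped_samples = [s for s in table.samples if s not in set(md_samples)]
    if not samples_keep:
        raise AlignmentError("table and metadata share no samples")
    if dropped_samples:
        logger.warning("dropping %d samples without metadata: %s", len(dropped_samples), dropped_samples)

    sub = table.subset(taxa=taxa_keep, samples=samples_keep)
    sub.is_relative = _autodetect_relative(sub.values)
    sheared = tree.shear(taxa_keep) if len(taxa_keep) < len(tip_names) else tree
    md = metadata[metadata["sample_id"].isin(samples_keep)].reset_index(drop=True)
    return Dataset(sub, sheared, md, dropped_taxa, dropped_samples)
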
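"""Shared data model and flat-file IO.

The whole pipeline runs on three carriers: a :class:`FeatureTable`
(samples x taxa abundance matrix), a :class:`SampleFrame` (per-sample
metadata plus environmental variables grouped into climatic / edaphic /
biotic blocks), and a rooted phylogeny with branch lengths
(:class:`skbio.TreeNode`).  Canonical on-disk formats are plain TSV for
tables and metadata, YAML for the block map, and newick for trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "FormatError",
    "ParameterError",
    "FeatureTable",
    "SampleFrame",
    "STAGES",
    "ENV_BLOCKS",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "to_proportions",
]

#: ordered successional stages: cyanobacterial < cyanobacteria-lichen < moss
STAGES = ("A", "C", "M")
ENV_BLOCKS = ("climatic", "edaphic", "biotic")


class FormatError(ValueError):
    """Raised when an input file or table violates the data model."""


class ParameterError(ValueError):
    """Raised when an operation receives invalid parameters."""


@dataclass
class FeatureTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa.  Non-negative.
    mode : {"counts", "proportions"}
        In proportions mode every row must sum to 1 (+- 1e-9).
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("feature table body must be numeric")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise FormatError(
                f"non-numeric cell at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if self.mode == "proportions":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                raise FormatError(
                    "proportions-mode rows must sum to 1; offending samples: "
                    f"{self.data.index[bad].tolist()}"
                )

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    @property
    def taxon_ids(self) -> list:
        return self.data.columns.tolist()

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def filter_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)], mode=self.mode)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.mode == other.mode and self.data.equals(other.data)


@dataclass
class SampleFrame:
    """Per-sample metadata with environmental blocks.

    ``data`` must carry columns ``site``, ``local_area``, ``stage`` and
    ``x_km`` (position along the sampling transect); every other numeric
    column is an environmental variable and must be assigned to exactly
    one block in ``blocks``.
    """

    data: pd.DataFrame
    blocks: dict = field(default_factory=dict)

    REQUIRED = ("site", "local_area", "stage", "x_km")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample ids in metadata")
        bad = set(self.data["stage"]) - set(STAGES)
        if bad:
            raise FormatError(
                f"stage labels must be one of {STAGES}; found {sorted(bad)}"
            )
        self.data = self.data.copy()
        self.data["stage"] = pd.Categorical(
            self.data["stage"], categories=list(STAGES), ordered=True
        )
        for block, cols in self.blocks.items():
            if block not in ENV_BLOCKS:
                raise FormatError(f"unknown environmental block {block!r}")
            absent = [c for c in cols if c not in self.data.columns]
            if absent:
                raise FormatError(f"block {block!r} names absent columns: {absent}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    def env_block(self, block: str) -> pd.DataFrame:
        """Numeric sub-frame for one environmental block."""
        if block not in self.blocks:
            raise ParameterError(f"no columns declared for block {block!r}")
        return self.data[self.blocks[block]].astype(float)

    def aligned_to(self, table: FeatureTable) -> "SampleFrame":
        """Reindex to the table's samples; every sample must be present."""
        missing = [s for s in table.sample_ids if s not in self.data.index]
        if missing:
            raise FormatError(f"samples without metadata rows: {missing}")
        return SampleFrame(self.data.loc[table.sample_ids], blocks=self.blocks)


def read_feature_table(path, orientation: str = "samples") -> FeatureTable:
    """Read a TSV feature table.

    ``orientation="samples"``: rows are samples (first column sample ids).
    ``orientation="taxa"``: rows are taxa (BIOM-TSV style, e.g. a
    ``#OTU ID`` first column); the table is transposed to samples x taxa.
    """
    if orientation not in ("samples", "taxa"):
        raise ParameterError(f"orientation must be 'samples' or 'taxa', got {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        df[col] = converted
    if df.isna().any().any():
        raise FormatError(f"missing values in feature table {path}")
    if orientation == "taxa":
        df = df.T
    return FeatureTable(df, mode="counts")


def write_feature_table(table: FeatureTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in km."""
    r = 6371.0088
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return float(2 * r * np.arcsin(np.sqrt(h)))


def read_metadata(path, block_map=None) -> SampleFrame:
    """Read TSV metadata; ``block_map`` is a YAML path or a dict mapping
    block name -> list of environmental column names.

    If the file carries ``lat``/``lon`` columns instead of ``x_km``, a
    1-D transect coordinate is derived as the great-circle distance of
    each sample from the first sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "x_km" not in df.columns and {"lat", "lon"} <= set(df.columns):
        ref = df.iloc[0]
        df["x_km"] = [
            great_circle_km(ref["lat"], ref["lon"], row["lat"], row["lon"])
            for _, row in df.iterrows()
        ]
    blocks = {}
    if block_map is not None:
        if isinstance(block_map, (str, Path)):
            with open(block_map) as fh:
                blocks = yaml.safe_load(fh)
        else:
            blocks = dict(block_map)
    return SampleFrame(df, blocks=blocks)


def write_metadata(frame: SampleFrame, path, block_map_path=None) -> None:
    frame.data.to_csv(path, sep="\t", index_label="sample_id")
    if block_map_path is not None:
        with open(block_map_path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in frame.blocks.items()}, fh)


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths default to 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"unparseable newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dups = sorted({t for t in tips if tips.count(t) > 1})
        raise FormatError(f"duplicate tip labels: {dups}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif not np.isfinite(node.length) or node.length < 0:
            raise FormatError(f"invalid branch length {node.length} at {node.name}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(
            f"{n_missing} branch lengths missing; defaulted to 0", stacklevel=2
        )
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def check_tree_covers(tree: TreeNode, taxa) -> None:
    """Raise if any taxon is not a tip of the tree."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(taxa) - tips)
    if missing:
        raise FormatError(f"taxa missing from tree: {missing}")


def to_proportions(table: FeatureTable) -> FeatureTable:
    """Convert a counts table to per-sample relative abundances.

    Idempotent on proportions-mode input.
    """
    if table.mode == "proportions":
        return table
    sums = table.data.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise FormatError(f"all-zero samples cannot be normalised: {zero.index.tolist()}")
    return FeatureTable(table.data.div(sums, axis=0), mode="proportions")


def euclidean_distance_matrix(df: pd.DataFrame) -> DistanceMatrix:
    """Plain pairwise Euclidean distances over the rows of ``df``."""
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(df.to_numpy(dtype=float))), ids=[str(i) for i in df.index])
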
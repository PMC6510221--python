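"""Core data model and file I/O: OTU tables, trees, metadata, rarefaction.

The central container is :class:`OtuTable`, a thin validated wrapper around a
``pandas.DataFrame`` of non-negative integer read counts oriented taxa x
samples. Trees are ``skbio.TreeNode`` objects read from newick; distance
matrices use ``skbio.DistanceMatrix``. All tabular formats are plain
tab-separated text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

# fixed per-stage offsets added to the master seed so each pipeline stage is
# independently reproducible
SEED_OFFSETS = {
    "simulate": 0,
    "rarefy": 101,
    "null_deviation": 202,
    "beta_nti": 303,
    "rc_bray": 404,
    "mantel": 505,
    "regression": 606,
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class MismatchError(KeyError):
    """Raised when taxon IDs in a table are missing from a tree or matrix."""


@dataclass(frozen=True)
class OtuTable:
    """Taxa x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by taxon ID, columns by sample ID, integer counts.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate taxon IDs in OTU table")
        if df.columns.has_duplicates:
            raise FormatError("duplicate sample IDs in OTU table")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric values in OTU table")
        if np.isnan(arr.astype(float)).any():
            raise FormatError("missing values in OTU table")
        if (arr < 0).any():
            raise FormatError("negative counts in OTU table")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("non-integer counts in OTU table")
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Counts as an integer array (taxa x samples)."""
        return self.data.to_numpy()

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """Count column for one sample, indexed by taxon ID."""
        return self.data[sample_id]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; columns with reads sum to 1."""
        totals = self.data.sum(axis=0)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise ValueError(f"samples with zero total reads: {empty}")
        return self.data / totals

    def subset_samples(self, sample_ids: list[str]) -> "OtuTable":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown sample IDs: {sorted(missing)}")
        return OtuTable(self.data[list(sample_ids)])

    def drop_empty_taxa(self) -> "OtuTable":
        return OtuTable(self.data.loc[self.data.sum(axis=1) > 0])


def read_otu_table(path, orientation: str = "taxa_rows") -> OtuTable:
    """Read a tab-separated count matrix.

    ``orientation='taxa_rows'`` expects taxa as rows and samples as columns
    (the common amplicon export); ``'samples_rows'`` reads the transpose.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # parse failure
        raise FormatError(f"cannot parse OTU table {path}: {exc}") from exc
    if orientation == "samples_rows":
        df = df.T
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return OtuTable(df)


def write_otu_table(table: OtuTable, path, orientation: str = "taxa_rows") -> None:
    df = table.data if orientation == "taxa_rows" else table.data.T
    df.to_csv(path, sep="\t")


def read_tree(path, strict: bool = False) -> TreeNode:
    """Read a rooted newick tree.

    Branches without a stated length are assigned 0 with a warning unless
    ``strict`` is set, in which case they are rejected.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"cannot parse newick file {path}: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if strict:
                raise FormatError("tree contains branches without lengths")
            node.length = 0.0
            n_missing += 1
    if tree.length is None:
        tree.length = 0.0
    for tip in tree.tips():
        tip.name = tip.name.strip() if tip.name else tip.name
    if n_missing:
        logger.warning("assigned length 0 to %d branches without lengths", n_missing)
    return tree


def read_metadata(path, group_column: str = "group") -> pd.DataFrame:
    """Read per-sample metadata: sample IDs, a site/group label, numeric variables.

    Returns a DataFrame indexed by sample ID with a ``group`` column and one
    numeric column per environmental variable. Empty cells become NaN and are
    excluded pairwise by downstream analyses.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:
        raise FormatError(f"cannot parse metadata file {path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    if df.index.has_duplicates:
        raise FormatError("duplicate sample IDs in metadata")
    if group_column not in df.columns:
        raise FormatError(f"metadata lacks required group column {group_column!r}")
    if df[group_column].isna().any() or (df[group_column].astype(str).str.len() == 0).any():
        raise FormatError("empty group labels in metadata")
    out = pd.DataFrame(index=df.index)
    out["group"] = df[group_column].astype(str)
    for col in df.columns:
        if col == group_column:
            continue
        out[col] = pd.to_numeric(df[col], errors="coerce")
    return out


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Draws follow the multivariate hypergeometric distribution (reads are
    removed from the sample as they are drawn). Samples with fewer than
    ``depth`` reads are dropped with a warning; if all samples fall below the
    depth an error is raised.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if dropped:
        logger.warning(
            "dropping %d samples below rarefaction depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not keep:
        raise ValueError(f"all samples have fewer than {depth} reads")
    cols = {}
    for s in keep:
        col = table.data[s].to_numpy()
        if totals[s] == depth:
            cols[s] = col
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    out = pd.DataFrame(cols, index=table.data.index)
    return OtuTable(out)


def write_long_table(records: pd.DataFrame, path) -> None:
    """Write a long-format result table as TSV with header."""
    if len(records) == 0:
        raise ValueError("refusing to write an empty result table")
    records.to_csv(path, sep="\t", index=False)


def read_long_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix rows and columns disagree")
    data = df.to_numpy(dtype=float)
    # symmetrize away write/read rounding noise before skbio validation
    if not np.allclose(data, data.T, atol=1e-12):
        raise FormatError("distance matrix is not symmetric")
    data = (data + data.T) / 2.0
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids=list(df.index))


def check_tree_covers_table(table: OtuTable, tree: TreeNode) -> None:
    """Raise MismatchError unless every table taxon is a tip of the tree."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise MismatchError(
            f"{len(missing)} table taxa missing from tree, e.g. {missing[:5]}"
        )
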
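"""Reading and writing the tabular and tree formats the pipeline consumes.

Canonical in-memory containers:

* abundance table — :class:`pandas.DataFrame`, samples as rows (index =
  sample ids), taxa as columns, non-negative numeric entries;
* sample metadata — :class:`pandas.DataFrame` indexed by sample id with
  categorical/numeric columns;
* phylogeny — :class:`skbio.TreeNode` with taxon-labelled leaves.

TSV files are tab-delimited UTF-8 with a header row. Readers validate the
container invariants (uniqueness, non-negativity) and raise
:class:`TableFormatError` naming the offending cell or identifier rather
than silently coercing.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import skbio


class TableFormatError(ValueError):
    """An input file violates the abundance-table or metadata contract."""


class TreeFormatError(ValueError):
    """A newick file cannot be parsed or violates the phylogeny contract."""


def _check_unique(values, what: str) -> None:
    counts = pd.Index(values).value_counts()
    dupes = counts[counts > 1]
    if len(dupes):
        raise TableFormatError(f"duplicate {what}: {', '.join(map(str, dupes.index[:5]))}")


def validate_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Validate abundance-table invariants, returning the table unchanged.

    Raises :class:`TableFormatError` on negative entries (naming the
    sample/taxon cell), duplicate sample ids or duplicate taxon ids.
    """
    _check_unique(table.index, "sample ids")
    _check_unique(table.columns, "taxon ids")
    values = table.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise TableFormatError(
            f"non-finite entry at sample {table.index[i]!r}, taxon {table.columns[j]!r}"
        )
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise TableFormatError(
            f"negative entry at sample {table.index[i]!r}, taxon {table.columns[j]!r}"
        )
    return table


def read_abundance_tsv(path, orientation: str = "samples_as_rows") -> pd.DataFrame:
    """Read a samples × taxa abundance table from TSV.

    Parameters
    ----------
    path : str or Path
        TSV file; first column holds row identifiers, header row holds
        column identifiers.
    orientation : {"samples_as_rows", "taxa_as_rows"}
        Microbiome TSVs ship in either orientation; ``taxa_as_rows``
        transposes on read. Samples-as-rows is canonical internally.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "taxa_as_rows":
        table = table.T
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    try:
        table = table.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric abundance entry in {path}: {exc}") from exc
    return validate_abundance(table)


def write_abundance_tsv(table: pd.DataFrame, path) -> None:
    """Write an abundance table as TSV, samples as rows."""
    validate_abundance(table)
    out = table.copy()
    # integer-valued tables round-trip as integers
    values = out.to_numpy(dtype=float)
    if np.all(values == np.floor(values)):
        out = out.astype(np.int64)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path, categorical: list[str] | None = None) -> pd.DataFrame:
    """Read sample metadata (first column = sample id) from TSV.

    Object-typed columns are converted to pandas categoricals; columns named
    in *categorical* are forced categorical even if numeric-looking. Missing
    values stay as ``NaN`` (never empty strings).
    """
    meta = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=True)
    meta.index = meta.index.astype(str)
    _check_unique(meta.index, "sample ids")
    for col in meta.columns:
        if (categorical and col in categorical) or meta[col].dtype == object:
            meta[col] = meta[col].astype("category")
    return meta


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def align_samples(table: pd.DataFrame, meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align a table and metadata on shared samples, reporting mismatches.

    Raises :class:`TableFormatError` listing samples present in the table
    but absent from the metadata (they are never silently dropped); metadata
    rows without a table sample are dropped, as questionnaires routinely
    cover more subjects than pass sequencing QC.
    """
    missing = table.index.difference(meta.index)
    if len(missing):
        raise TableFormatError(
            f"{len(missing)} samples missing from metadata: {', '.join(missing[:5])}"
        )
    return table, meta.loc[table.index]


def read_newick(path) -> skbio.TreeNode:
    """Read a rooted newick tree with branch lengths.

    Validates the phylogeny contract: unique leaf names, finite
    non-negative branch lengths (missing root length is treated as 0).
    Parse failures raise :class:`TreeFormatError` carrying the parser's
    character-position diagnostic.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise TreeFormatError(f"unparseable newick in {path}: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: skbio.TreeNode) -> skbio.TreeNode:
    names = [leaf.name for leaf in tree.tips()]
    if any(n is None for n in names):
        raise TreeFormatError("tree has unnamed leaves")
    _check_unique_tree(names)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise TreeFormatError(f"invalid branch length {node.length!r} at {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    return tree


def _check_unique_tree(names) -> None:
    seen = set()
    for n in names:
        if n in seen:
            raise TreeFormatError(f"duplicate leaf label {n!r}")
        seen.add(n)


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def tree_to_newick(tree: skbio.TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def read_distance_tsv(path) -> skbio.DistanceMatrix:
    """Read a square (or lower-triangle) TSV distance matrix."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():  # lower-triangle form: mirror
        values = np.where(np.isnan(values), 0.0, values)
        values = values + values.T
    return skbio.DistanceMatrix(values, ids=[str(i) for i in frame.index])


def write_distance_tsv(dm: skbio.DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t", index_label="sample_id")


__all__ = [
    "TableFormatError",
    "TreeFormatError",
    "validate_abundance",
    "validate_tree",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "align_samples",
    "read_newick",
    "write_newick",
    "tree_to_newick",
    "read_distance_tsv",
    "write_distance_tsv",
]
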
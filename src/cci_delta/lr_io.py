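"""Readers and writers for the pipeline's tabular formats.

Formats
-------
counts.tsv
    Genes x cells TSV of normalized expression; first column holds gene
    ids, remaining column headers are cell ids.
meta.tsv
    Per-cell metadata TSV; first column is the cell id and the cell-type
    label is taken from a ``cell_type`` column (falling back to the
    second column).
LR database
    TSV with columns ``id, partner_a, partner_b, a_is_receptor,
    b_is_receptor``.
significant means
    The wide dialect consumed downstream: one row per interaction id,
    one column per ``source|target`` cell-type pair, each cell holding
    the significant mean score or left empty.  A long-form TSV (columns
    ``interaction_id, source, target, mean_score, p_value, significant``)
    is auto-detected by header and accepted as well.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    SIG_COLUMNS,
    AnnotatedExpression,
    FormatError,
    LRDatabase,
    SignificantMeans,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_expression_mtx",
    "read_lr_database",
    "write_lr_database",
    "read_significant_means",
    "write_significant_means",
    "write_scored_table",
]

_BOOL_STRINGS = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _parse_bool(value, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return bool(value)
    key = str(value).strip().lower()
    if key in _BOOL_STRINGS:
        return _BOOL_STRINGS[key]
    raise FormatError(f"cannot parse {value!r} in column {column!r} as a boolean")


def _read_meta(meta_path: str | os.PathLike) -> pd.Series:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if meta.shape[1] < 2:
        raise FormatError("metadata table needs at least cell-id and cell-type columns")
    cell_col = meta.columns[0]
    type_col = "cell_type" if "cell_type" in meta.columns else meta.columns[1]
    labels = pd.Series(meta[type_col].to_numpy(), index=meta[cell_col].to_numpy())
    if labels.index.has_duplicates:
        dups = labels.index[labels.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate cell ids in metadata: {dups[:5]}")
    return labels


def _assemble(matrix: pd.DataFrame, labels: pd.Series) -> AnnotatedExpression:
    """Align a cells x genes frame with a per-cell label series (meta order)."""
    missing_in_counts = [c for c in labels.index if c not in matrix.index]
    if missing_in_counts:
        raise FormatError(
            f"cells in metadata but not in counts: {missing_in_counts[:5]}"
        )
    extra_in_counts = [c for c in matrix.index if c not in labels.index]
    if extra_in_counts:
        raise FormatError(
            f"cells in counts but not in metadata: {extra_in_counts[:5]}"
        )
    matrix = matrix.loc[labels.index]
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        bad = matrix.index[np.any(values < 0, axis=1)].tolist()
        raise FormatError(f"negative expression values for cells: {bad[:5]}")
    return AnnotatedExpression(
        values=values,
        cell_ids=matrix.index,
        gene_ids=matrix.columns,
        cell_type=labels,
    )


def read_expression(
    counts_path: str | os.PathLike, meta_path: str | os.PathLike
) -> AnnotatedExpression:
    """Load a genes x cells counts TSV plus metadata into memory.

    Cells present in only one of the two files raise a
    :class:`FormatError` naming the offending ids; cell order is
    normalized to the metadata order.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids in counts: {dups[:5]}")
    labels = _read_meta(meta_path)
    return _assemble(counts.T, labels)


def write_expression(
    expr: AnnotatedExpression,
    counts_path: str | os.PathLike,
    meta_path: str | os.PathLike,
) -> None:
    """Write the genes x cells counts TSV and the metadata TSV."""
    expr.to_frame().T.to_csv(counts_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"cell": expr.cell_ids, "cell_type": expr.cell_type.to_numpy()}
    ).to_csv(meta_path, sep="\t", index=False)


def read_expression_mtx(
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    cells_path: str | os.PathLike,
    meta_path: str | os.PathLike,
) -> AnnotatedExpression:
    """Load a MatrixMarket triplet (genes x cells) with row/col name files."""
    mat = scipy.io.mmread(os.fspath(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    frame = pd.DataFrame(mat, index=genes, columns=cells)
    return _assemble(frame.T, _read_meta(meta_path))


def read_lr_database(path: str | os.PathLike) -> LRDatabase:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id", "partner_a", "partner_b", "a_is_receptor", "b_is_receptor"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"LR database missing columns: {missing}")
    dup = df["id"][df["id"].duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"duplicate interaction ids: {dup[:5]}")
    for col in ("a_is_receptor", "b_is_receptor"):
        df[col] = [_parse_bool(v, col) for v in df[col]]
    try:
        return LRDatabase.from_frame(df)
    except ValueError as exc:  # e.g. self-pairs
        raise FormatError(str(exc)) from exc


def write_lr_database(db: LRDatabase, path: str | os.PathLike) -> None:
    db.to_frame().to_csv(path, sep="\t", index=False)


def _pair_columns(columns: list[str]) -> list[tuple[str, str]]:
    pairs = []
    for col in columns:
        if col.count("|") != 1:
            raise FormatError(
                f"malformed pair column {col!r}: expected exactly one '|' "
                "separating source and target cell types"
            )
        source, target = col.split("|")
        if not source or not target:
            raise FormatError(f"malformed pair column {col!r}: empty cell type")
        pairs.append((source, target))
    return pairs


def read_significant_means(
    path: str | os.PathLike, alpha: float = 0.05, condition: str = ""
) -> SignificantMeans:
    """Parse a significant-means table (wide or long dialect, by header).

    Wide dialect: each non-empty ``source|target`` cell yields one record
    with ``significant=True`` and an unrecorded (NaN) p-value.  Long
    dialect: columns are read as-is.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"interaction_id", "source", "target"}.issubset(df.columns):
        for col in ("mean_score", "p_value", "significant"):
            if col not in df.columns:
                raise FormatError(f"long-form table missing column {col!r}")
        long = df.copy()
        long["mean_score"] = long["mean_score"].astype(float)
        long["p_value"] = long["p_value"].astype(float)
        long["significant"] = [_parse_bool(v, "significant") for v in long["significant"]]
        return SignificantMeans(long[SIG_COLUMNS], condition=condition, alpha=alpha)

    id_col = df.columns[0]
    pairs = _pair_columns(list(df.columns[1:]))
    records: list[dict] = []
    for row in df.itertuples(index=False):
        interaction_id = str(row[0])
        for (source, target), raw in zip(pairs, row[1:]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw) == "":
                continue
            records.append(
                {
                    "interaction_id": interaction_id,
                    "source": source,
                    "target": target,
                    "mean_score": float(raw),
                    "p_value": np.nan,
                    "significant": True,
                }
            )
    table = pd.DataFrame(records, columns=SIG_COLUMNS)
    _ = id_col  # first column name is not semantically constrained
    return SignificantMeans(table, condition=condition, alpha=alpha)


def write_significant_means(sig: SignificantMeans, path: str | os.PathLike) -> None:
    """Write the wide dialect: significant records fill cells, others stay empty.

    Row order is interaction-id lexicographic; columns are ordered by
    (source, target) lexicographically, restricted to pairs carrying at
    least one significant record.  Output is byte-deterministic.
    """
    df = sig.table[sig.table["significant"]]
    ids = sorted(df["interaction_id"].unique())
    pairs = sorted(set(zip(df["source"], df["target"])))
    wide = pd.DataFrame("", index=pd.Index(ids, name="id"),
                        columns=[f"{s}|{t}" for s, t in pairs], dtype=object)
    for row in df.itertuples(index=False):
        wide.at[row.interaction_id, f"{row.source}|{row.target}"] = repr(
            float(row.mean_score)
        )
    wide.to_csv(path, sep="\t")


def write_scored_table(sig: SignificantMeans, path: str | os.PathLike) -> None:
    """Write the long dialect with p-values, sorted for determinism."""
    df = sig.table.sort_values(
        ["interaction_id", "source", "target"], kind="mergesort"
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
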
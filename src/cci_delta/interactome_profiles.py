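"""Interaction count matrices, per-cell-type interaction profiles, and
their Spearman rank correlations.

The count matrix tabulates significant records per ordered (as-source,
as-target) cell-type pair.  Profile matrices flatten each cell type's
interactions into a binary vector keyed by ``interaction_id|counterpart``
so that two cell types can be compared by which interactions they share;
rank correlations of the rows (cell types) or columns then quantify how
alike two interaction repertoires are.  Autocrine records (source ==
target) are counted like any other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import SignificantMeans

__all__ = [
    "InteractionCountMatrix",
    "ProfileMatrix",
    "CorrelationMatrix",
    "build_count_matrix",
    "build_profile_matrix",
    "profile_correlation",
]

Axis = Literal["as-source", "as-target"]
CorrAxis = Literal["rows", "columns"]


@dataclass
class InteractionCountMatrix:
    """Square cell-type x cell-type table of significant-record counts."""

    values: pd.DataFrame
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.values.columns):
            raise ValueError("row and column cell-type sets must be identical")
        if np.any(self.values.to_numpy() < 0):
            raise ValueError("counts must be non-negative")
        self.values = self.values.astype(int)

    @property
    def grand_total(self) -> int:
        return int(self.values.to_numpy().sum())

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ProfileMatrix:
    """Binary cell-type x interaction-occurrence-key matrix.

    With ``axis='as-source'``, entry (c, ``i|t``) is 1 iff interaction i
    from source c to target t is significant; ``'as-target'`` swaps the
    roles (rows are targets, keys name the source counterpart).
    """

    values: pd.DataFrame
    axis: Axis
    condition: str = ""

    def __post_init__(self) -> None:
        if self.axis not in ("as-source", "as-target"):
            raise ValueError(f"invalid axis {self.axis!r}")
        vals = self.values.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("profile entries must be binary")
        self.values = self.values.astype(int)


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations with an explicit defined-mask.

    ``defined`` is False wherever either vector has zero rank variance;
    the corresponding ``values`` entries are NaN rather than a silent 0.
    """

    values: pd.DataFrame
    defined: pd.DataFrame
    axis: CorrAxis

    def __post_init__(self) -> None:
        if not (
            self.values.index.equals(self.defined.index)
            and self.values.columns.equals(self.defined.columns)
        ):
            raise ValueError("values and defined-mask must share axes")


def _universe(sig: SignificantMeans, cell_types: Iterable[str] | None) -> list[str]:
    if cell_types is None:
        return sig.cell_types()
    declared = sorted(set(cell_types))
    observed = set(sig.table.loc[sig.table["significant"], "source"]) | set(
        sig.table.loc[sig.table["significant"], "target"]
    )
    extra = observed - set(declared)
    if extra:
        raise ValueError(f"cell types in table but not declared: {sorted(extra)}")
    return declared


def build_count_matrix(
    sig: SignificantMeans, cell_types: Iterable[str] | None = None
) -> InteractionCountMatrix:
    """Count significant records per (as-source, as-target) pair.

    Declared-but-inactive cell types appear as all-zero rows/columns.
    """
    types = _universe(sig, cell_types)
    df = sig.table[sig.table["significant"]]
    counts = (
        df.groupby(["source", "target"], sort=False).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame(dtype=int)
    )
    counts = counts.reindex(index=types, columns=types, fill_value=0)
    return InteractionCountMatrix(values=counts, condition=sig.condition)


def build_profile_matrix(
    sig: SignificantMeans, axis: Axis, cell_types: Iterable[str] | None = None
) -> ProfileMatrix:
    """Binary interaction profile per cell type on the chosen axis.

    Columns are restricted to occurrence keys seen at least once.
    """
    if axis not in ("as-source", "as-target"):
        raise ValueError(f"invalid axis {axis!r}: use 'as-source' or 'as-target'")
    types = _universe(sig, cell_types)
    df = sig.table[sig.table["significant"]]
    own, other = ("source", "target") if axis == "as-source" else ("target", "source")
    keys = sorted(
        {f"{i}|{c}" for i, c in zip(df["interaction_id"], df[other])}
    )
    mat = pd.DataFrame(0, index=types, columns=keys, dtype=int)
    for row in df.itertuples(index=False):
        key = f"{row.interaction_id}|{getattr(row, other)}"
        mat.at[getattr(row, own), key] = 1
    return ProfileMatrix(values=mat, axis=axis, condition=sig.condition)


def profile_correlation(
    matrix: ProfileMatrix | InteractionCountMatrix | pd.DataFrame,
    axis: CorrAxis = "rows",
) -> CorrelationMatrix:
    """Pairwise Spearman rho (average ranks for ties) over rows or columns.

    Zero-variance vectors give explicitly undefined (NaN + masked)
    entries instead of propagating silently.
    """
    if isinstance(matrix, (ProfileMatrix, InteractionCountMatrix)):
        frame = matrix.values
    else:
        frame = pd.DataFrame(matrix)
    if axis not in ("rows", "columns"):
        raise ValueError(f"invalid axis {axis!r}: use 'rows' or 'columns'")
    data = frame.to_numpy(dtype=float)
    names = frame.index if axis == "rows" else frame.columns
    vectors = data if axis == "rows" else data.T
    n = vectors.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vectors to correlate")

    variable = vectors.std(axis=1) > 0
    # rank (average ties) then Pearson; constant vectors give NaN rows
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, vectors)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.atleast_2d(rho)
    defined = np.outer(variable, variable)
    rho = np.where(defined, rho, np.nan)
    np.fill_diagonal(rho, np.where(variable, 1.0, np.nan))
    return CorrelationMatrix(
        values=pd.DataFrame(rho, index=names, columns=names),
        defined=pd.DataFrame(defined, index=names, columns=names),
        axis=axis,
    )
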
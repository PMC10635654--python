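"""Core in-memory containers shared across the pipeline.

The pipeline moves four kinds of objects between stages: the
ligand-receptor catalogue (:class:`LRDatabase`), the labelled expression
matrix (:class:`AnnotatedExpression`), the per-condition table of
permutation-scored interactions (:class:`SignificantMeans`), and the
derived matrices/graphs defined in their own modules.  Everything here is
a thin, validated wrapper around numpy/pandas so that the file formats
(:mod:`cci_delta.lr_io`) and the statistics (:mod:`cci_delta.lr_scoring`)
stay decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "LRPair",
    "LRDatabase",
    "AnnotatedExpression",
    "SignificantMeans",
    "SIG_COLUMNS",
]

# cell-type names are opaque strings, but '|' is reserved for the
# composite "source|target" column headers of the wide table dialect
FORBIDDEN_LABEL_CHAR = "|"


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected layout."""


@dataclass(frozen=True)
class LRPair:
    """One catalogued ligand-receptor pair.

    A pair is *directed* when exactly one partner is flagged as the
    receptor: the interaction then only makes sense with the ligand
    expressed in the source cell type and the receptor in the target.
    Pairs with both or neither partner flagged are *undirected* and are
    evaluated in both orientations downstream.
    """

    id: str
    partner_a: str
    partner_b: str
    a_is_receptor: bool
    b_is_receptor: bool

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("interaction id must be non-empty")
        if not self.partner_a or not self.partner_b:
            raise ValueError(f"partners of {self.id!r} must be non-empty")
        if self.partner_a == self.partner_b:
            raise ValueError(f"self-pair not allowed: {self.id!r} ({self.partner_a})")

    @property
    def directed(self) -> bool:
        return self.a_is_receptor != self.b_is_receptor

    @property
    def ligand(self) -> str:
        """Non-receptor partner of a directed pair."""
        if not self.directed:
            raise ValueError(f"{self.id!r} is undirected; no unique ligand")
        return self.partner_b if self.a_is_receptor else self.partner_a

    @property
    def receptor(self) -> str:
        if not self.directed:
            raise ValueError(f"{self.id!r} is undirected; no unique receptor")
        return self.partner_a if self.a_is_receptor else self.partner_b

    def oriented(self) -> tuple[str, str]:
        """(source-side gene, target-side gene) for a (source, target) record.

        Directed pairs put the ligand on the source side; undirected pairs
        use the (partner_a, partner_b) orientation by convention -- the
        reversed assignment belongs to the mirrored (target, source) record.
        """
        if self.directed:
            return self.ligand, self.receptor
        return self.partner_a, self.partner_b


class LRDatabase:
    """Ordered collection of :class:`LRPair` with unique ids."""

    def __init__(self, pairs: Iterable[LRPair]):
        self._pairs: list[LRPair] = list(pairs)
        seen: set[str] = set()
        for p in self._pairs:
            if p.id in seen:
                raise ValueError(f"duplicate interaction id {p.id!r}")
            seen.add(p.id)
        self._by_id = {p.id: p for p in self._pairs}

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[LRPair]:
        return iter(self._pairs)

    def __contains__(self, interaction_id: str) -> bool:
        return interaction_id in self._by_id

    def __getitem__(self, interaction_id: str) -> LRPair:
        try:
            return self._by_id[interaction_id]
        except KeyError:
            raise KeyError(f"unknown interaction id {interaction_id!r}") from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LRDatabase) and self._pairs == other._pairs

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self._pairs]

    @property
    def genes(self) -> list[str]:
        """All partner genes, in first-appearance order, deduplicated."""
        out: list[str] = []
        seen: set[str] = set()
        for p in self._pairs:
            for g in (p.partner_a, p.partner_b):
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self._pairs],
                "partner_a": [p.partner_a for p in self._pairs],
                "partner_b": [p.partner_b for p in self._pairs],
                "a_is_receptor": [p.a_is_receptor for p in self._pairs],
                "b_is_receptor": [p.b_is_receptor for p in self._pairs],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LRDatabase":
        required = {"id", "partner_a", "partner_b", "a_is_receptor", "b_is_receptor"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"LR database missing columns: {sorted(missing)}")
        return cls(
            LRPair(
                id=str(r.id),
                partner_a=str(r.partner_a),
                partner_b=str(r.partner_b),
                a_is_receptor=bool(r.a_is_receptor),
                b_is_receptor=bool(r.b_is_receptor),
            )
            for r in df.itertuples(index=False)
        )


@dataclass
class AnnotatedExpression:
    """Normalized cells x genes expression matrix with per-cell labels.

    ``values[i, j]`` is the (non-negative, already normalized) expression
    of gene ``gene_ids[j]`` in cell ``cell_ids[i]``; ``cell_type[i]`` is
    that cell's population label.
    """

    values: np.ndarray
    cell_ids: pd.Index
    gene_ids: pd.Index
    cell_type: pd.Series

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (cells x genes)")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cell ids / {len(self.gene_ids)} gene ids"
            )
        if self.cell_ids.has_duplicates:
            raise ValueError("duplicate cell ids")
        if self.gene_ids.has_duplicates:
            raise ValueError("duplicate gene ids")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        self.cell_type = pd.Series(self.cell_type)
        if len(self.cell_type) != n_cells:
            raise ValueError("one cell-type label required per cell")
        self.cell_type.index = self.cell_ids
        self.cell_type = self.cell_type.astype(str)
        bad = [t for t in self.cell_type.unique() if FORBIDDEN_LABEL_CHAR in t]
        if bad:
            raise ValueError(f"'|' is forbidden in cell-type names: {bad}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> list[str]:
        """Distinct cell-type labels, sorted."""
        return sorted(self.cell_type.unique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


# canonical long-form column order for scored interaction tables
SIG_COLUMNS = ["interaction_id", "source", "target", "mean_score", "p_value", "significant"]


@dataclass
class SignificantMeans:
    """Per-(interaction, source, target) scored records for one condition.

    ``table`` is a long-form frame with columns ``interaction_id``,
    ``source``, ``target``, ``mean_score``, ``p_value``, ``significant``.
    A wide file parsed from disk carries only the significant cells, in
    which case ``p_value`` is NaN.  ``alpha`` records the threshold used
    to set the ``significant`` flag (None before thresholding).
    """

    table: pd.DataFrame
    condition: str = ""
    alpha: float | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing = [c for c in SIG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"scored table missing columns: {missing}")
        df = df[SIG_COLUMNS].copy()
        df["mean_score"] = df["mean_score"].astype(float)
        df["p_value"] = df["p_value"].astype(float)
        df["significant"] = df["significant"].astype(bool)
        if np.any(df["mean_score"].to_numpy() < 0):
            raise ValueError("mean scores must be non-negative")
        p = df["p_value"].to_numpy()
        ok = np.isnan(p) | ((p >= 0) & (p <= 1))
        if not ok.all():
            raise ValueError("p-values must lie in [0, 1]")
        dup = df.duplicated(subset=["interaction_id", "source", "target"])
        if dup.any():
            first = df.loc[dup, ["interaction_id", "source", "target"]].iloc[0]
            raise ValueError(f"duplicate record key {tuple(first)}")
        if self.alpha is not None:
            flagged = df.loc[df["significant"] & ~df["p_value"].isna(), "p_value"]
            if np.any(flagged.to_numpy() > self.alpha):
                raise ValueError("significant record with p-value above alpha")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def significant(self) -> "SignificantMeans":
        """Copy restricted to records with ``significant == True``."""
        return SignificantMeans(
            self.table[self.table["significant"]].reset_index(drop=True),
            condition=self.condition,
            alpha=self.alpha,
        )

    def triples(self, significant_only: bool = True) -> set[tuple[str, str, str]]:
        """Set of (source, target, interaction_id) keys."""
        df = self.table[self.table["significant"]] if significant_only else self.table
        return set(zip(df["source"], df["target"], df["interaction_id"]))

    def cell_types(self) -> list[str]:
        return sorted(set(self.table["source"]) | set(self.table["target"]))
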
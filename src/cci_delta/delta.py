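"""Differential interactome classification between two conditions.

Every (source, target, interaction) triple of the declared universe --
all ordered cell-type pairs crossed with the full interaction catalogue
-- is classified by its significance at the earlier vs later condition:

    stable  significant in both
    lost    significant only in the earlier condition
    gained  significant only in the later condition
    absent  significant in neither

The four classes partition the universe, and two margin identities hold
exactly: |stable| + |lost| equals the earlier condition's significant
count, |stable| + |gained| the later one's.  On top of the partition the
module summarizes per-population percent changes of interaction counts
and ranks the top-changing reactions by the absolute change of the
significant mean score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .datatypes import LRDatabase, SignificantMeans
from .interactome_profiles import InteractionCountMatrix

__all__ = [
    "DeltaClassification",
    "ChangeSummary",
    "classify",
    "percent_change",
    "top_changing",
    "CLASSES",
]

CLASSES = ("absent", "stable", "lost", "gained")
Scope = Literal["pair", "as-source", "as-target", "population-total"]

# ranking priority for tied change scores
_CLASS_PRIORITY = {"gained": 0, "lost": 1, "stable": 2, "absent": 3}


@dataclass
class DeltaClassification:
    """Partition of the triple universe with per-triple mean scores.

    ``table`` columns: source, target, interaction_id, class,
    mean_early, mean_late (significant mean scores; 0 where the triple
    was not significant in that condition).
    """

    table: pd.DataFrame
    condition_early: str = ""
    condition_late: str = ""

    def _set(self, cls: str) -> set[tuple[str, str, str]]:
        df = self.table[self.table["class"] == cls]
        return set(zip(df["source"], df["target"], df["interaction_id"]))

    @property
    def stable_set(self):
        return self._set("stable")

    @property
    def lost_set(self):
        return self._set("lost")

    @property
    def gained_set(self):
        return self._set("gained")

    @property
    def absent_set(self):
        return self._set("absent")

    def class_counts(self) -> dict[str, int]:
        counts = self.table["class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def pair_summary(self) -> pd.DataFrame:
        """Per (source, target) pair: count of each class."""
        out = (
            self.table.groupby(["source", "target"])["class"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=list(CLASSES), fill_value=0)
        )
        out.columns.name = None
        return out


def classify(
    sig_early: SignificantMeans,
    sig_late: SignificantMeans,
    db: LRDatabase,
    cell_types: Iterable[str],
) -> DeltaClassification:
    """Classify every universe triple as absent/stable/lost/gained."""
    types = sorted(set(cell_types))
    type_set = set(types)
    for label, sig in (("earlier", sig_early), ("later", sig_late)):
        undeclared = (set(sig.table["source"]) | set(sig.table["target"])) - type_set
        if undeclared:
            raise ValueError(
                f"cell types in the {label} table but not declared: {sorted(undeclared)}"
            )
        unknown = set(sig.table["interaction_id"]) - set(db.ids)
        if unknown:
            raise ValueError(
                f"interaction ids in the {label} table but not in the database: "
                f"{sorted(unknown)[:5]}"
            )

    def sig_means(sig: SignificantMeans) -> dict[tuple[str, str, str], float]:
        df = sig.table[sig.table["significant"]]
        return {
            (s, t, i): m
            for s, t, i, m in zip(
                df["source"], df["target"], df["interaction_id"], df["mean_score"]
            )
        }

    early = sig_means(sig_early)
    late = sig_means(sig_late)

    rows = []
    for s in types:
        for t in types:
            for i in db.ids:
                key = (s, t, i)
                in_early = key in early
                in_late = key in late
                if in_early and in_late:
                    cls = "stable"
                elif in_early:
                    cls = "lost"
                elif in_late:
                    cls = "gained"
                else:
                    cls = "absent"
                rows.append(
                    (s, t, i, cls, early.get(key, 0.0), late.get(key, 0.0))
                )
    table = pd.DataFrame(
        rows,
        columns=["source", "target", "interaction_id", "class", "mean_early", "mean_late"],
    )
    return DeltaClassification(
        table=table,
        condition_early=sig_early.condition,
        condition_late=sig_late.condition,
    )


@dataclass
class ChangeSummary:
    """Interaction-count changes at one aggregation scope.

    ``table`` columns: count_early, count_later, percent_change (NaN
    with ``defined=False`` when the earlier count is zero -- never an
    infinity).
    """

    table: pd.DataFrame
    scope: Scope


def percent_change(
    cm_early: InteractionCountMatrix,
    cm_late: InteractionCountMatrix,
    scope: Scope = "population-total",
) -> ChangeSummary:
    """Percent change of interaction counts between two conditions.

    Scopes: ``pair`` (each ordered source/target pair), ``as-source``
    (row margins), ``as-target`` (column margins), ``population-total``
    (a population's as-source plus as-target counts, autocrine diagonal
    counted once).
    """
    if list(cm_early.values.index) != list(cm_late.values.index):
        raise ValueError("count matrices must share the same cell-type universe")
    early = cm_early.values
    late = cm_late.values
    if scope == "pair":
        idx = pd.MultiIndex.from_product(
            [early.index, early.columns], names=["source", "target"]
        )
        e = early.stack().reindex(idx)
        l = late.stack().reindex(idx)
    elif scope == "as-source":
        e, l = early.sum(axis=1), late.sum(axis=1)
    elif scope == "as-target":
        e, l = early.sum(axis=0), late.sum(axis=0)
    elif scope == "population-total":
        diag_e = pd.Series(np.diag(early), index=early.index)
        diag_l = pd.Series(np.diag(late), index=late.index)
        e = early.sum(axis=1) + early.sum(axis=0) - diag_e
        l = late.sum(axis=1) + late.sum(axis=0) - diag_l
    else:
        raise ValueError(f"invalid scope {scope!r}")
    e = e.astype(int)
    l = l.astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(e > 0, (l - e) / np.where(e > 0, e, 1) * 100.0, np.nan)
    table = pd.DataFrame(
        {
            "count_early": e,
            "count_later": l,
            "percent_change": pct,
            "defined": (e > 0).to_numpy(),
        },
        index=e.index,
    )
    return ChangeSummary(table=table, scope=scope)


def top_changing(delta: DeltaClassification, k: int = 25) -> pd.DataFrame:
    """Rank reactions by |later mean - earlier mean|.

    Missing (non-significant) means count as 0.  Ties break by class
    priority gained > lost > stable > absent, then lexicographically by
    interaction id, source, target.  Returns the top ``k`` rows with
    their change scores and classes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = delta.table.copy()
    df["change_score"] = (df["mean_late"] - df["mean_early"]).abs()
    df["_priority"] = df["class"].map(_CLASS_PRIORITY)
    df = df.sort_values(
        ["change_score", "_priority", "interaction_id", "source", "target"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).drop(columns="_priority")
    return df.head(k).reset_index(drop=True)
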
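"""Synthetic expression data with planted cell-cell interactions.

The generator emulates the inputs of the scoring stage: a ligand-receptor
catalogue, a normalized cells x genes matrix with per-cell cell-type
labels, and a pair of conditions related by a controlled gain/loss
turnover of "active" interactions.  An interaction triple
``(source type, target type, interaction id)`` is made active by
multiplying the ligand's mean in the source type and the receptor's mean
in the target type by ``effect_size``; cells then draw log-normal
multiplicative noise around their type's mean, so values are strictly
positive and the planted fold-change is preserved in expectation.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning; identical configurations
produce identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import AnnotatedExpression, LRDatabase, LRPair

__all__ = [
    "SimulationConfig",
    "DeltaTruth",
    "generate_lr_database",
    "sample_active_set",
    "generate_expression",
    "generate_condition_pair",
    "triple_universe",
    "default_cell_types",
    "write_delta_truth",
    "read_delta_truth",
]

Triple = tuple[str, str, str]  # (source type, target type, interaction id)


def default_cell_types(n: int) -> list[str]:
    return [f"CT{k:02d}" for k in range(1, n + 1)]


def triple_universe(cell_types: Iterable[str], db: LRDatabase) -> set[Triple]:
    """All ordered (source, target, interaction) triples, autocrine included."""
    types = list(cell_types)
    return {(s, t, i) for s in types for t in types for i in db.ids}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    ``active_set`` holds the planted (source, target, interaction id)
    triples; ``effect_size`` is the fold elevation of the corresponding
    ligand/receptor cluster means; ``dispersion`` is the sigma of the
    log-normal multiplicative noise; ``gain_rate``/``loss_rate`` control
    the interaction turnover between the two generated conditions.
    """

    lr_db: LRDatabase
    active_set: frozenset[Triple] = frozenset()
    n_cell_types: int = 6
    cells_per_type: int = 60
    n_background_genes: int = 50
    effect_size: float = 6.0
    baseline_mean: float = 1.0
    dispersion: float = 0.3
    gain_rate: float = 0.0
    loss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.cells_per_type < 2:
            raise ValueError("need at least 2 cells per type")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValueError("baseline_mean must be > 0 and dispersion >= 0")
        for name in ("gain_rate", "loss_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        types = set(self.cell_types)
        for s, t, i in self.active_set:
            if i not in self.lr_db:
                raise ValueError(f"active interaction id {i!r} not in the LR database")
            if s not in types or t not in types:
                raise ValueError(f"active triple ({s}, {t}, {i}) names an unknown cell type")
        object.__setattr__(self, "active_set", frozenset(self.active_set))

    @property
    def cell_types(self) -> list[str]:
        return default_cell_types(self.n_cell_types)


@dataclass(frozen=True)
class DeltaTruth:
    """Planted partition of the triple universe across two conditions."""

    stable_set: frozenset[Triple]
    lost_set: frozenset[Triple]
    gained_set: frozenset[Triple]
    absent_set: frozenset[Triple]

    def __post_init__(self) -> None:
        sets = [self.stable_set, self.lost_set, self.gained_set, self.absent_set]
        total = sum(len(s) for s in sets)
        union = frozenset().union(*sets)
        if total != len(union):
            raise ValueError("truth sets must be pairwise disjoint")

    @property
    def universe(self) -> frozenset[Triple]:
        return self.stable_set | self.lost_set | self.gained_set | self.absent_set

    @property
    def active_early(self) -> frozenset[Triple]:
        return self.stable_set | self.lost_set

    @property
    def active_late(self) -> frozenset[Triple]:
        return self.stable_set | self.gained_set


def generate_lr_database(
    n_pairs: int,
    frac_undirected: float = 0.0,
    seed: int = 0,
    *,
    ligand_pool: int | None = None,
    receptor_pool: int | None = None,
) -> LRDatabase:
    """Generate a synthetic ligand-receptor catalogue.

    By default every pair gets its own two genes (``GAxxxx``/``GBxxxx``),
    so planted effects never collide across interactions.  Passing
    ``ligand_pool``/``receptor_pool`` sizes instead draws partners from
    shared gene pools (``LGxxxx``/``RCxxxx``), mimicking real catalogues
    where one ligand engages several receptors.

    Each pair is undirected with probability ``frac_undirected`` (both
    receptor flags cleared); directed pairs flag exactly one partner,
    chosen at random, as the receptor.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if not 0 <= frac_undirected <= 1:
        raise ValueError("frac_undirected must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pooled = ligand_pool is not None or receptor_pool is not None
    if pooled:
        if not ligand_pool or not receptor_pool:
            raise ValueError("both gene pool sizes must be positive")
        if ligand_pool * receptor_pool < n_pairs:
            raise ValueError("gene pools too small for n_pairs distinct pairs")
        combos: set[tuple[int, int]] = set()
        partners: list[tuple[str, str]] = []
        while len(partners) < n_pairs:
            a = int(rng.integers(ligand_pool))
            b = int(rng.integers(receptor_pool))
            if (a, b) in combos:
                continue
            combos.add((a, b))
            partners.append((f"LG{a:04d}", f"RC{b:04d}"))
    else:
        partners = [(f"GA{k:04d}", f"GB{k:04d}") for k in range(n_pairs)]

    undirected = rng.random(n_pairs) < frac_undirected
    receptor_is_a = rng.random(n_pairs) < 0.5
    pairs = []
    for k, (a, b) in enumerate(partners):
        if undirected[k]:
            flags = (False, False)
        else:
            flags = (True, False) if receptor_is_a[k] else (False, True)
        pairs.append(
            LRPair(
                id=f"CPI-SYN{k:05d}",
                partner_a=a,
                partner_b=b,
                a_is_receptor=flags[0],
                b_is_receptor=flags[1],
            )
        )
    return LRDatabase(pairs)


def sample_active_set(
    db: LRDatabase,
    cell_types: Iterable[str],
    n_active: int,
    seed: int = 0,
    distinct_ids: bool = True,
) -> frozenset[Triple]:
    """Sample planted triples uniformly.

    With ``distinct_ids`` (default) each triple uses its own interaction
    id, which keeps the planted signal triple-specific: because the
    co-expression score is a sum of marginal cluster means, reusing an
    id across triples would elevate half of the score of every triple
    sharing its source or target.
    """
    types = list(cell_types)
    rng = np.random.default_rng(seed)
    if distinct_ids:
        if n_active > len(db):
            raise ValueError("n_active exceeds number of interaction ids")
        ids = rng.choice(db.ids, size=n_active, replace=False)
        triples = set()
        for i in ids:
            s = types[int(rng.integers(len(types)))]
            t = types[int(rng.integers(len(types)))]
            triples.add((s, t, str(i)))
        return frozenset(triples)
    universe = sorted(triple_universe(types, db))
    if n_active > len(universe):
        raise ValueError("n_active exceeds the triple universe")
    idx = rng.choice(len(universe), size=n_active, replace=False)
    return frozenset(universe[j] for j in idx)


def _gene_ids(config: SimulationConfig) -> list[str]:
    background = [f"BG{j:04d}" for j in range(config.n_background_genes)]
    return config.lr_db.genes + background


def _mean_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Per-gene per-type mean matrix with planted elevations applied.

    Each (gene, type) slot is elevated at most once even if several
    active triples imply it, so the planted fold change is exactly
    ``effect_size``.
    """
    genes = _gene_ids(config)
    types = config.cell_types
    means = pd.DataFrame(config.baseline_mean, index=genes, columns=types, dtype=float)
    elevated: set[tuple[str, str]] = set()
    for s, t, i in sorted(config.active_set):
        g_source, g_target = config.lr_db[i].oriented()
        elevated.add((g_source, s))
        elevated.add((g_target, t))
    for gene, ctype in elevated:
        means.at[gene, ctype] *= config.effect_size
    return means


def generate_expression(
    config: SimulationConfig, seed: int | np.random.SeedSequence | None = None
) -> AnnotatedExpression:
    """Draw one labelled expression matrix from the configured model.

    Cell values are ``mean * LogNormal(-dispersion^2 / 2, dispersion)``
    so that the expectation equals the planted mean exactly.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    means = _mean_matrix(config)
    types = config.cell_types
    n_cells = config.n_cell_types * config.cells_per_type
    labels = np.repeat(types, config.cells_per_type)
    cell_ids = [
        f"{t}_c{j:04d}" for t in types for j in range(config.cells_per_type)
    ]
    sigma = config.dispersion
    per_cell_means = means.T.loc[labels].to_numpy()  # cells x genes
    if sigma > 0:
        noise = rng.lognormal(
            mean=-0.5 * sigma**2, sigma=sigma, size=per_cell_means.shape
        )
    else:
        noise = np.ones_like(per_cell_means)
    values = per_cell_means * noise
    return AnnotatedExpression(
        values=values,
        cell_ids=pd.Index(cell_ids),
        gene_ids=pd.Index(means.index),
        cell_type=pd.Series(labels, index=cell_ids),
    )


def generate_condition_pair(
    config: SimulationConfig,
) -> tuple[AnnotatedExpression, AnnotatedExpression, DeltaTruth]:
    """Generate two conditions linked by planted gain/loss turnover.

    Condition 2's active set drops each condition-1 triple with
    probability ``loss_rate`` and adds ``Binomial(|active|, gain_rate)``
    fresh triples drawn uniformly from the inactive pool (gains sized
    relative to the active set so that turnover stays controlled).
    Gains prefer interaction ids not already in play, falling back to
    arbitrary inactive triples only if fresh ids run out.
    """
    root = np.random.SeedSequence(config.seed)
    ss_turnover, ss_expr1, ss_expr2 = root.spawn(3)
    rng = np.random.default_rng(ss_turnover)

    active1 = sorted(config.active_set)
    lost = {t for t in active1 if rng.random() < config.loss_rate}
    stable = set(active1) - lost

    universe = triple_universe(config.cell_types, config.lr_db)
    n_gain = int(rng.binomial(len(active1), config.gain_rate)) if active1 else 0
    used_ids = {i for _, _, i in active1}
    fresh_pool = sorted(
        t for t in universe - set(active1) if t[2] not in used_ids
    )
    fallback_pool = sorted(universe - set(active1) - set(fresh_pool))
    gained: set[Triple] = set()
    if n_gain > 0:
        take_fresh = min(n_gain, len(fresh_pool))
        if take_fresh:
            # one id at most once among gains, to keep gains triple-specific
            by_id: dict[str, list[Triple]] = {}
            for t in fresh_pool:
                by_id.setdefault(t[2], []).append(t)
            ids = sorted(by_id)
            chosen_ids = rng.choice(ids, size=min(take_fresh, len(ids)), replace=False)
            for i in chosen_ids:
                options = by_id[str(i)]
                gained.add(options[int(rng.integers(len(options)))])
        remaining = n_gain - len(gained)
        if remaining > 0 and fallback_pool:
            idx = rng.choice(len(fallback_pool), size=min(remaining, len(fallback_pool)), replace=False)
            gained.update(fallback_pool[j] for j in idx)

    absent = universe - stable - lost - gained
    truth = DeltaTruth(
        stable_set=frozenset(stable),
        lost_set=frozenset(lost),
        gained_set=frozenset(gained),
        absent_set=frozenset(absent),
    )
    expr1 = generate_expression(config, seed=ss_expr1)
    config2 = replace(config, active_set=frozenset(stable | gained))
    expr2 = generate_expression(config2, seed=ss_expr2)
    return expr1, expr2, truth


def write_delta_truth(truth: DeltaTruth, path: str | os.PathLike) -> None:
    payload = {
        name: sorted(map(list, getattr(truth, f"{name}_set")))
        for name in ("stable", "lost", "gained", "absent")
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_delta_truth(path: str | os.PathLike) -> DeltaTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return DeltaTruth(
        **{
            f"{name}_set": frozenset(tuple(t) for t in payload[name])
            for name in ("stable", "lost", "gained", "absent")
        }
    )
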
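"""Standard synthetic benchmarks: null calibration and planted-truth recovery.

Two canonical experiments exercise the whole inference chain under known
ground truth:

``null_calibration``
    Expression with no planted effect (effect_size = 1) over 6 cell
    types x 60 cells and 100 interactions (3600 scored triples).  Under
    the null the permutation p-values are uniform, so the fraction of
    triples with p <= 0.05 estimates the test's type-I error.

``planted_recovery``
    Two conditions with planted interactions (effect_size 6, 6 cell
    types x 100 cells, 900 active triples with private interaction ids,
    gain = loss = 0.2, 200 permutations).  Reports the power on planted
    triples, the {stable, lost, gained} macro recall restricted to the
    planted (ever-active) triples -- all of which pass the power
    threshold -- and one-vs-rest balanced accuracies of the gained/lost
    calls over the full triple universe.

Benchmark sizes are fixed: they are the package's reference conditions,
chosen so that each run completes in minutes on one CPU while keeping
the sampling error of every reported fraction below about one percent.
"""

from __future__ import annotations

import numpy as np

from .delta import classify
from .lr_scoring import ScoringConfig, score_expression
from .synthetic_data import (
    SimulationConfig,
    generate_condition_pair,
    generate_expression,
    generate_lr_database,
    sample_active_set,
)

__all__ = ["null_calibration", "planted_recovery"]


def null_calibration(
    seed: int = 0,
    n_interactions: int = 100,
    n_cell_types: int = 6,
    cells_per_type: int = 60,
    n_permutations: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Fraction of null triples called significant at ``alpha``."""
    rng = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    db = generate_lr_database(n_interactions, frac_undirected=0.3, seed=int(rng[0]))
    cfg = SimulationConfig(
        lr_db=db,
        active_set=frozenset(),
        n_cell_types=n_cell_types,
        cells_per_type=cells_per_type,
        n_background_genes=50,
        effect_size=1.0,
        dispersion=0.3,
        seed=int(rng[1]),
    )
    expr = generate_expression(cfg)
    scfg = ScoringConfig(
        n_permutations=n_permutations, alpha=alpha, min_frac_expressing=0.10,
        seed=int(rng[1]),
    )
    sig = score_expression(expr, db, scfg)
    n_scored = len(sig)
    n_sig = int(sig.table["significant"].sum())
    return {
        "n_scored_triples": n_scored,
        "n_significant": n_sig,
        "fraction_significant": n_sig / n_scored if n_scored else float("nan"),
        "alpha": alpha,
    }


def _balanced_accuracy(called: set, truth: set, universe: set) -> float:
    """One-vs-rest balanced accuracy of a set-valued call."""
    positives = truth
    negatives = universe - truth
    tp = len(called & positives)
    tn = len(negatives - called)
    sens = tp / len(positives) if positives else float("nan")
    spec = tn / len(negatives) if negatives else float("nan")
    return 0.5 * (sens + spec)


def planted_recovery(
    seed: int = 0,
    n_interactions: int = 1800,
    n_active: int = 900,
    n_cell_types: int = 6,
    cells_per_type: int = 100,
    effect_size: float = 6.0,
    gain_rate: float = 0.2,
    loss_rate: float = 0.2,
    n_permutations: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Score a planted two-condition dataset and compare with the truth."""
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    db = generate_lr_database(n_interactions, frac_undirected=0.3, seed=int(seeds[0]))
    types = [f"CT{k:02d}" for k in range(1, n_cell_types + 1)]
    active = sample_active_set(db, types, n_active, seed=int(seeds[1]))
    cfg = SimulationConfig(
        lr_db=db,
        active_set=active,
        n_cell_types=n_cell_types,
        cells_per_type=cells_per_type,
        n_background_genes=100,
        effect_size=effect_size,
        dispersion=0.3,
        gain_rate=gain_rate,
        loss_rate=loss_rate,
        seed=int(seeds[2]),
    )
    expr_early, expr_late, truth = generate_condition_pair(cfg)
    scfg = ScoringConfig(
        n_permutations=n_permutations, alpha=alpha, min_frac_expressing=0.10,
        seed=int(seeds[3]),
    )
    sig_early = score_expression(expr_early, db, scfg, condition="day2")
    sig_late = score_expression(expr_late, db, scfg, condition="day30")

    called_early = sig_early.triples()
    power = (
        len(called_early & truth.active_early) / len(truth.active_early)
        if truth.active_early
        else float("nan")
    )

    dc = classify(sig_early, sig_late, db, cell_types=types)
    called = {"stable": dc.stable_set, "lost": dc.lost_set, "gained": dc.gained_set}
    truth_sets = {
        "stable": set(truth.stable_set),
        "lost": set(truth.lost_set),
        "gained": set(truth.gained_set),
    }
    planted = set(truth.active_early | truth.active_late)
    recalls = {}
    for cls in ("stable", "lost", "gained"):
        t = truth_sets[cls] & planted
        recalls[cls] = len(called[cls] & t) / len(t) if t else float("nan")
    macro_recall = float(np.mean([recalls[c] for c in ("stable", "lost", "gained")]))

    universe = set(truth.universe)
    ba_gained = _balanced_accuracy(dc.gained_set, truth_sets["gained"], universe)
    ba_lost = _balanced_accuracy(dc.lost_set, truth_sets["lost"], universe)

    return {
        "n_planted_early": len(truth.active_early),
        "n_lost_true": len(truth.lost_set),
        "n_gained_true": len(truth.gained_set),
        "power_early": power,
        "recall_stable": recalls["stable"],
        "recall_lost": recalls["lost"],
        "recall_gained": recalls["gained"],
        "macro_recall_planted": macro_recall,
        "balanced_accuracy_gained": ba_gained,
        "balanced_accuracy_lost": ba_lost,
        "n_significant_early": len(called_early),
        "n_significant_late": len(sig_late.triples()),
    }
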
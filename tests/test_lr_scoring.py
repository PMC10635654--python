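"""Scoring statistics: cluster summaries, scores, permutation p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cci_delta import (
    AnnotatedExpression,
    LRDatabase,
    LRPair,
    ScoringConfig,
    cluster_stats,
    interaction_score,
    permutation_pvalues,
    significant_means,
)
from oracles import cluster_mean_loop, enumerate_pvalues


def _expr(values, labels, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    cells = [f"c{i}" for i in range(values.shape[0])]
    return AnnotatedExpression(
        values=values,
        cell_ids=pd.Index(cells),
        gene_ids=pd.Index(genes),
        cell_type=pd.Series(labels, index=cells),
    )


class TestClusterStats:
    def test_single_cell_single_type(self):
        stats = cluster_stats(_expr([[5.0]], ["A"]))
        assert stats.mean_expr.at["g0", "A"] == 5.0
        assert stats.frac_expressing.at["g0", "A"] == 1.0

    def test_zero_inflated_group_arithmetic(self):
        stats = cluster_stats(_expr([[0.0], [0.0], [4.0]], ["A", "A", "A"]))
        assert stats.mean_expr.at["g0", "A"] == pytest.approx(4 / 3)
        assert stats.frac_expressing.at["g0", "A"] == pytest.approx(1 / 3)

    def test_matches_per_cell_loop_exactly(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 2, size=(50, 20)) * (rng.random((50, 20)) > 0.3)
        labels = rng.choice(["A", "B", "C"], size=50)
        stats = cluster_stats(_expr(values, labels))
        mean, frac = cluster_mean_loop(values, labels)
        for t in mean:
            assert np.array_equal(stats.mean_expr[t].to_numpy(), mean[t])
            assert np.array_equal(stats.frac_expressing[t].to_numpy(), frac[t])


class TestInteractionScore:
    def test_arithmetic_mean_of_cluster_means(self):
        stats = cluster_stats(
            _expr([[2.0, 0.0], [2.0, 0.0], [0.0, 4.0], [0.0, 4.0]],
                  ["A", "A", "B", "B"], genes=["L1", "R1"])
        )
        pair = LRPair("CPI-1", "L1", "R1", False, True)
        assert interaction_score(stats, pair, "A", "B") == 3.0
        assert interaction_score(stats, pair, "B", "A") == 0.0

    def test_missing_gene_raises(self):
        stats = cluster_stats(_expr([[1.0]], ["A"], genes=["L1"]))
        pair = LRPair("CPI-1", "L1", "RX", False, True)
        with pytest.raises(ValueError, match="RX"):
            interaction_score(stats, pair, "A", "A")

    def test_matches_bruteforce_over_all_triples(self, toy_db, toy_expression):
        stats = cluster_stats(toy_expression)
        labels = toy_expression.cell_type.to_numpy()
        values = toy_expression.values
        gi = {g: j for j, g in enumerate(toy_expression.gene_ids)}
        for pair in toy_db:
            if pair.id == "CPI-U" and "M2" not in gi:
                continue
            for s in ("A", "B"):
                for t in ("A", "B"):
                    gs, gt = pair.oriented()
                    if gs not in gi or gt not in gi:
                        continue
                    expected = 0.5 * (
                        values[labels == s, gi[gs]].mean()
                        + values[labels == t, gi[gt]].mean()
                    )
                    assert interaction_score(stats, pair, s, t) == pytest.approx(
                        expected, abs=1e-14
                    )


class TestPermutationPvalues:
    def test_observed_beating_all_permutations_gives_add_one_floor(self):
        # strong planted signal: ligand only in A, receptor only in B
        values = np.zeros((20, 2))
        values[:10, 0] = 5.0
        values[10:, 1] = 5.0
        labels = ["A"] * 10 + ["B"] * 10
        db = LRDatabase([LRPair("CPI-1", "g0", "g1", False, True)])
        cfg = ScoringConfig(n_permutations=99, min_frac_expressing=0.0, seed=1)
        scored = permutation_pvalues(_expr(values, labels), db, cfg)
        row = scored.table.set_index(["source", "target"]).loc[("A", "B")]
        assert row["p_value"] == pytest.approx(0.01)

    def test_identical_cells_are_exchangeable(self):
        values = np.ones((8, 2))
        labels = ["A"] * 4 + ["B"] * 4
        db = LRDatabase([LRPair("CPI-1", "g0", "g1", False, True)])
        cfg = ScoringConfig(n_permutations=50, min_frac_expressing=0.0, seed=0)
        scored = permutation_pvalues(_expr(values, labels), db, cfg)
        assert (scored.table["p_value"] == 1.0).all()

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0.5, 2.0, size=(6, 4))
        labels = ["A", "A", "A", "B", "B", "B"]
        db = LRDatabase(
            [
                LRPair("CPI-1", "g0", "g1", False, True),
                LRPair("CPI-2", "g2", "g3", False, True),
            ]
        )
        # one cell-index permutation per distinct label arrangement: slot k
        # (whose fixed label is labels[k]) receives a cell j with arr[j]
        # equal to labels[k], so cell j ends up carrying label arr[j]
        perms = []
        for arr in sorted(set(itertools.permutations(labels))):
            by_label = {}
            for j, lab in enumerate(arr):
                by_label.setdefault(lab, []).append(j)
            take = {lab: iter(cells) for lab, cells in by_label.items()}
            perms.append([next(take[labels[k]]) for k in range(len(labels))])
        cfg = ScoringConfig(n_permutations=len(perms), min_frac_expressing=0.0, seed=0)
        scored = permutation_pvalues(_expr(values, labels), db, cfg, permutations=perms)
        expected = enumerate_pvalues(
            values, labels, {"CPI-1": (0, 1), "CPI-2": (2, 3)}, min_frac=0.0
        )
        assert len(scored) == len(expected)
        for row in scored.table.itertuples(index=False):
            key = (row.interaction_id, row.source, row.target)
            assert row.p_value == pytest.approx(expected[key], abs=1e-12)

    def test_pvalues_always_in_unit_interval_open_at_zero(self, toy_db, toy_expression):
        cfg = ScoringConfig(n_permutations=25, min_frac_expressing=0.0, seed=3)
        scored = permutation_pvalues(toy_expression, toy_db, cfg)
        p = scored.table["p_value"].to_numpy()
        assert (p > 0).all() and (p <= 1).all()

    def test_monotone_in_observed_score(self):
        # same null sample; larger observed score can only shrink the count
        rng = np.random.default_rng(5)
        null_scores = rng.normal(size=200)
        for lo, hi in [(-1.0, 0.5), (0.0, 1.0), (0.5, 2.0)]:
            p_lo = (1 + np.sum(null_scores >= lo)) / 201
            p_hi = (1 + np.sum(null_scores >= hi)) / 201
            assert p_hi <= p_lo

    def test_expression_filter_drops_triples(self):
        values = np.zeros((10, 2))
        values[:5, 0] = 1.0  # ligand expressed only in A
        values[5:, 1] = 1.0  # receptor expressed only in B
        labels = ["A"] * 5 + ["B"] * 5
        db = LRDatabase([LRPair("CPI-1", "g0", "g1", False, True)])
        cfg = ScoringConfig(n_permutations=10, min_frac_expressing=0.5, seed=0)
        scored = permutation_pvalues(_expr(values, labels), db, cfg)
        # only (A, B) passes the filter: ligand silent in B, receptor silent in A
        assert set(zip(scored.table["source"], scored.table["target"])) == {("A", "B")}

    def test_single_label_rejected(self):
        db = LRDatabase([LRPair("CPI-1", "g0", "g1", False, True)])
        with pytest.raises(ValueError, match="2 distinct"):
            permutation_pvalues(
                _expr([[1, 1], [1, 1]], ["A", "A"]), db, ScoringConfig(n_permutations=5)
            )

    def test_determinism_under_fixed_seed(self, toy_db, toy_expression):
        cfg = ScoringConfig(n_permutations=40, min_frac_expressing=0.0, seed=9)
        a = permutation_pvalues(toy_expression, toy_db, cfg)
        b = permutation_pvalues(toy_expression, toy_db, cfg)
        assert a.table.equals(b.table)


class TestSignificantMeans:
    @pytest.mark.parametrize(
        "p,alpha,expected",
        [(0.04, 0.05, True), (0.05, 0.05, True), (0.051, 0.05, False)],
    )
    def test_threshold_boundary_included(self, p, alpha, expected):
        table = pd.DataFrame(
            [["CPI-1", "A", "B", 1.0, p, False]],
            columns=["interaction_id", "source", "target", "mean_score", "p_value", "significant"],
        )
        from cci_delta import SignificantMeans

        scored = SignificantMeans(table)
        out = significant_means(scored, ScoringConfig(alpha=alpha))
        assert bool(out.table["significant"].iloc[0]) is expected

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScoringConfig(n_permutations=0)
        with pytest.raises(ValueError):
            ScoringConfig(alpha=1.5)
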
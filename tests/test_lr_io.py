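"""Round trips and format-error behaviour of the tabular readers/writers."""

import numpy as np
import pandas as pd
import pytest

from cci_delta import FormatError, SignificantMeans, generate_lr_database
from cci_delta import lr_io
from cci_delta.datatypes import SIG_COLUMNS


def _write(path, text):
    path.write_text(text)
    return path


class TestExpressionIO:
    def test_toy_parse_shape_and_label_order(self, tmp_path):
        counts = _write(
            tmp_path / "counts.tsv",
            "gene\tc1\tc2\tc3\tc4\n"
            "g1\t1\t2\t3\t4\n"
            "g2\t0\t0\t1\t1\n"
            "g3\t5\t5\t5\t5\n",
        )
        meta = _write(
            tmp_path / "meta.tsv",
            "cell\tcell_type\nc4\tB\nc3\tB\nc2\tA\nc1\tA\n",
        )
        expr = lr_io.read_expression(counts, meta)
        assert expr.values.shape == (4, 3)
        assert list(expr.cell_ids) == ["c4", "c3", "c2", "c1"]  # meta order
        assert list(expr.cell_type) == ["B", "B", "A", "A"]
        assert expr.values[0, 0] == 4.0

    def test_meta_cell_missing_from_counts_names_it(self, tmp_path):
        counts = _write(tmp_path / "c.tsv", "gene\tc1\ng1\t1\n")
        meta = _write(tmp_path / "m.tsv", "cell\tcell_type\nc1\tA\ncX\tB\n")
        with pytest.raises(FormatError, match="cX"):
            lr_io.read_expression(counts, meta)

    def test_counts_cell_missing_from_meta_names_it(self, tmp_path):
        counts = _write(tmp_path / "c.tsv", "gene\tc1\tcY\ng1\t1\t2\n")
        meta = _write(tmp_path / "m.tsv", "cell\tcell_type\nc1\tA\n")
        with pytest.raises(FormatError, match="cY"):
            lr_io.read_expression(counts, meta)

    def test_negative_values_rejected(self, tmp_path):
        counts = _write(tmp_path / "c.tsv", "gene\tc1\ng1\t-1\n")
        meta = _write(tmp_path / "m.tsv", "cell\tcell_type\nc1\tA\n")
        with pytest.raises(FormatError, match="negative"):
            lr_io.read_expression(counts, meta)

    def test_roundtrip_preserves_values(self, tmp_path, toy_expression):
        lr_io.write_expression(
            toy_expression, tmp_path / "counts.tsv", tmp_path / "meta.tsv"
        )
        back = lr_io.read_expression(tmp_path / "counts.tsv", tmp_path / "meta.tsv")
        assert np.allclose(back.values, toy_expression.values, atol=1e-12)
        assert list(back.cell_type) == list(toy_expression.cell_type)
        assert list(back.gene_ids) == list(toy_expression.gene_ids)

    def test_mtx_roundtrip(self, tmp_path, toy_expression):
        import scipy.io
        import scipy.sparse

        mtx = tmp_path / "m.mtx"
        scipy.io.mmwrite(
            mtx, scipy.sparse.coo_matrix(toy_expression.values.T)
        )
        (tmp_path / "genes.tsv").write_text(
            "\n".join(toy_expression.gene_ids) + "\n"
        )
        (tmp_path / "cells.tsv").write_text(
            "\n".join(toy_expression.cell_ids) + "\n"
        )
        meta = pd.DataFrame(
            {"cell": toy_expression.cell_ids, "cell_type": toy_expression.cell_type.to_numpy()}
        )
        meta.to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        back = lr_io.read_expression_mtx(
            mtx.with_suffix(".mtx"), tmp_path / "genes.tsv",
            tmp_path / "cells.tsv", tmp_path / "meta.tsv",
        )
        assert np.allclose(back.values, toy_expression.values, atol=1e-10)


class TestLRDatabaseIO:
    def test_single_row_directed(self, tmp_path):
        path = _write(
            tmp_path / "db.tsv",
            "id\tpartner_a\tpartner_b\ta_is_receptor\tb_is_receptor\n"
            "CPI-1\tFLT1\tVEGFB\tFalse\tTrue\n",
        )
        db = lr_io.read_lr_database(path)
        assert len(db) == 1
        assert db["CPI-1"].directed
        assert db["CPI-1"].ligand == "FLT1"

    def test_duplicate_ids_rejected(self, tmp_path):
        path = _write(
            tmp_path / "db.tsv",
            "id\tpartner_a\tpartner_b\ta_is_receptor\tb_is_receptor\n"
            "CPI-1\tA\tB\tFalse\tTrue\n"
            "CPI-1\tC\tD\tFalse\tTrue\n",
        )
        with pytest.raises(FormatError, match="CPI-1"):
            lr_io.read_lr_database(path)

    def test_missing_column_rejected(self, tmp_path):
        path = _write(tmp_path / "db.tsv", "id\tpartner_a\nCPI-1\tA\n")
        with pytest.raises(FormatError, match="partner_b"):
            lr_io.read_lr_database(path)

    def test_synthetic_roundtrip_identical(self, tmp_path):
        db = generate_lr_database(200, 0.4, seed=9)
        lr_io.write_lr_database(db, tmp_path / "db.tsv")
        assert lr_io.read_lr_database(tmp_path / "db.tsv") == db


def _sig(records, condition="day2", alpha=0.05):
    table = pd.DataFrame(records, columns=SIG_COLUMNS)
    return SignificantMeans(table, condition=condition, alpha=alpha)


class TestSignificantMeansIO:
    def test_wide_count_of_nonempty_cells(self, tmp_path):
        path = _write(
            tmp_path / "sig.txt",
            "id\tA|B\tB|A\tA|A\n"
            "CPI-1\t1.5\t\t2.0\n"
            "CPI-2\t\t0.7\t\n",
        )
        sig = lr_io.read_significant_means(path)
        assert len(sig) == 3
        assert sig.triples() == {("A", "B", "CPI-1"), ("A", "A", "CPI-1"), ("B", "A", "CPI-2")}

    def test_all_empty_table_gives_zero_records(self, tmp_path):
        path = _write(tmp_path / "sig.txt", "id\tA|B\nCPI-1\t\n")
        assert len(lr_io.read_significant_means(path)) == 0

    def test_malformed_pair_header_rejected(self, tmp_path):
        path = _write(tmp_path / "sig.txt", "id\tAB\nCPI-1\t1\n")
        with pytest.raises(FormatError, match="AB"):
            lr_io.read_significant_means(path)

    def test_empty_input_writes_header_only(self, tmp_path):
        sig = _sig([])
        lr_io.write_significant_means(sig, tmp_path / "out.txt")
        lines = (tmp_path / "out.txt").read_text().splitlines()
        assert len(lines) == 1

    def test_single_record_single_cell(self, tmp_path):
        sig = _sig([("CPI-1", "A", "B", 2.5, 0.01, True)])
        lr_io.write_significant_means(sig, tmp_path / "out.txt")
        lines = (tmp_path / "out.txt").read_text().splitlines()
        assert lines[0] == "id\tA|B"
        assert lines[1] == "CPI-1\t2.5"

    def test_roundtrip_record_set_identical(self, tmp_path):
        rng = np.random.default_rng(4)
        records = [
            (f"CPI-{k}", s, t, float(rng.uniform(0.1, 5)), 0.01, True)
            for k in range(20)
            for s, t in [("A", "B"), ("B", "C")]
            if rng.random() < 0.6
        ]
        sig = _sig(records)
        lr_io.write_significant_means(sig, tmp_path / "out.txt")
        back = lr_io.read_significant_means(tmp_path / "out.txt")
        assert back.triples() == sig.triples()
        merged = back.table.merge(
            sig.table, on=["interaction_id", "source", "target"], suffixes=("_r", "_w")
        )
        assert np.allclose(merged["mean_score_r"], merged["mean_score_w"])

    def test_reserialization_is_byte_identical(self, tmp_path):
        sig = _sig(
            [
                ("CPI-2", "B", "A", 0.123456789012345, 0.02, True),
                ("CPI-1", "A", "B", 2.5, 0.01, True),
                ("CPI-1", "B", "B", 1.0, 0.2, False),
            ]
        )
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        lr_io.write_significant_means(sig, p1)
        lr_io.write_significant_means(lr_io.read_significant_means(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_long_dialect_autodetected(self, tmp_path):
        sig = _sig(
            [
                ("CPI-1", "A", "B", 2.5, 0.01, True),
                ("CPI-1", "B", "A", 0.4, 0.8, False),
            ]
        )
        lr_io.write_scored_table(sig, tmp_path / "long.tsv")
        back = lr_io.read_significant_means(tmp_path / "long.tsv")
        assert len(back) == 2
        assert back.triples() == {("A", "B", "CPI-1")}
        assert back.table["p_value"].notna().all()
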
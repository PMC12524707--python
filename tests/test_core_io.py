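import numpy as np
import pandas as pd
import pytest

from gmtrepurpose import core_io
from gmtrepurpose.core_io import (
    CountMatrix,
    ExpressionMatrix,
    FormatError,
    GeneSetCollection,
    ScoreTable,
    SurvivalTable,
)

from conftest import make_expr


class TestExpressionMatrix:
    def test_tsv_parse_shape(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\tS1\tS2\nA\t1\t2\nB\t3\t4\nC\t5\t6\n")
        expr = core_io.read_expression_matrix(p)
        assert expr.shape == (3, 2)
        assert expr.gene_ids == ["A", "B", "C"]

    def test_gct_header_body_mismatch_rejected(self, tmp_path):
        p = tmp_path / "m.gct"
        body = "Name\tDescription\tS1\tS2\n" + "".join(
            f"G{i}\tna\t1\t2\n" for i in range(4)
        )
        p.write_text("#1.2\n5\t2\n" + body)
        with pytest.raises(FormatError, match="declares"):
            core_io.read_expression_matrix(p)

    @pytest.mark.parametrize("fmt", ["tsv", "gct"])
    def test_round_trip(self, tmp_path, rng, fmt):
        expr = make_expr(rng.standard_normal((5, 3)))
        p = tmp_path / f"m.{fmt}"
        core_io.write_expression_matrix(expr, p, format=fmt)
        back = core_io.read_expression_matrix(p, format=fmt)
        assert back.gene_ids == expr.gene_ids
        assert np.allclose(back.values, expr.values, atol=1e-12)

    def test_duplicate_gene_rows_collapsed_by_mean(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                          index=["A", "A", "B"], columns=["S1", "S2"])
        expr = ExpressionMatrix(df)
        assert expr.gene_ids == ["A", "B"]
        assert np.allclose(expr.data.loc["A"], [2.0, 3.0])

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\tS1\tS2\nA\t1\toops\nB\t3\t4\n")
        with pytest.raises(FormatError):
            core_io.read_expression_matrix(p)


class TestGeneSets:
    def test_parse_two_sets(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("SET1\tdesc1\tA\tB\nSET2\tdesc2\tC\n")
        coll = core_io.read_gene_sets(p)
        assert len(coll) == 2
        assert coll["SET1"] == ["A", "B"]

    def test_line_without_genes_rejected(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("SETX\tdesc\n")
        with pytest.raises(FormatError, match=":1"):
            core_io.read_gene_sets(p)

    def test_case_insensitive_deduplication(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("SET1\tdesc\ta2m\tA2m\tTP53\n")
        coll = core_io.read_gene_sets(p)
        assert coll["SET1"] == ["A2M", "TP53"]

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection({"S1": ["A", "B"], "S2": ["C"]}, {"S1": "x", "S2": "y"})
        p = tmp_path / "s.gmt"
        core_io.write_gene_sets(coll, p)
        assert core_io.read_gene_sets(p).sets == coll.sets


class TestEdgeList:
    def _write(self, tmp_path, rows):
        p = tmp_path / "e.tsv"
        p.write_text("nodeA\tnodeB\tcombined_score\n" +
                     "".join(f"{a}\t{b}\t{s}\n" for a, b, s in rows))
        return p

    def test_strict_confidence_threshold(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", 0.9), ("B", "C", 0.7), ("C", "D", 0.5)])
        g = core_io.read_edge_list(p, min_confidence=0.7)
        assert g.n_edges() == 1  # only the 0.9 edge survives the strict > 0.7 rule

    def test_string_scale_autodetected(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", 900), ("B", "C", 750)])
        g = core_io.read_edge_list(p, min_confidence=0.7)
        assert g.graph.edges["A", "B"]["confidence"] == pytest.approx(0.9)

    def test_self_loop_dropped(self, tmp_path):
        p = self._write(tmp_path, [("A", "A", 0.99)])
        g = core_io.read_edge_list(p, min_confidence=0.7)
        assert g.n_edges() == 0

    def test_negative_score_rejected(self, tmp_path):
        p = self._write(tmp_path, [("A", "B", -0.1)])
        with pytest.raises(FormatError):
            core_io.read_edge_list(p)

    def test_threshold_monotone(self, tmp_path, rng):
        rows = [(f"N{i}", f"N{i + 1}", round(rng.uniform(0, 1), 3)) for i in range(30)]
        p = self._write(tmp_path, rows)
        sizes = [core_io.read_edge_list(p, min_confidence=t).n_edges()
                 for t in (0.0, 0.25, 0.5, 0.75, 0.9)]
        assert sizes == sorted(sizes, reverse=True)


class TestOtherTables:
    def test_signature_library_round_trip(self, tmp_path, rng):
        meta = pd.DataFrame(
            {"compound": ["c1", "c1", "c2"], "cell_line": ["L1", "L2", "L1"],
             "pert_type": ["compound"] * 3},
            index=["p1", "p2", "p3"],
        )
        z = pd.DataFrame(rng.standard_normal((3, 10)), index=meta.index,
                         columns=[f"G{i}" for i in range(10)])
        lib = core_io.PerturbagenLibrary(meta=meta, zscores=z)
        core_io.write_signature_library(lib, tmp_path / "z.tsv", tmp_path / "m.tsv")
        back = core_io.read_signature_library(tmp_path / "z.tsv", tmp_path / "m.tsv")
        assert back.perturbagen_ids == lib.perturbagen_ids
        assert np.allclose(back.zscores, lib.zscores, atol=1e-12)

    def test_metadata_row_mismatch_rejected(self, tmp_path, rng):
        meta = pd.DataFrame({"compound": ["c1"], "cell_line": ["L1"],
                             "pert_type": ["compound"]}, index=["p1"])
        z = pd.DataFrame(rng.standard_normal((2, 4)), index=["p1", "p2"])
        meta.to_csv(tmp_path / "m.tsv", sep="\t", index_label="perturbagen")
        z.to_csv(tmp_path / "z.tsv", sep="\t", index_label="perturbagen")
        with pytest.raises(FormatError, match="metadata"):
            core_io.read_signature_library(tmp_path / "z.tsv", tmp_path / "m.tsv")

    def test_negative_survival_time_rejected(self):
        with pytest.raises(FormatError, match="times"):
            SurvivalTable(pd.DataFrame({"time": [5.0, -1.0], "event": [1, 0]},
                                       index=["a", "b"]))

    def test_bad_event_value_rejected(self):
        with pytest.raises(FormatError, match="event"):
            SurvivalTable(pd.DataFrame({"time": [5.0, 2.0], "event": [1, 2]},
                                       index=["a", "b"]))

    def test_duplicate_compound_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            ScoreTable(pd.DataFrame({"x": [1.0, 2.0]}, index=["c1", "c1"]))

    def test_fingerprint_round_trip(self, tmp_path):
        fps = core_io.FingerprintSet(pd.DataFrame([[1, 0, 1], [0, 1, 1]],
                                                  index=["c1", "c2"]))
        core_io.write_fingerprints(fps, tmp_path / "f.tsv")
        back = core_io.read_fingerprints(tmp_path / "f.tsv")
        assert (back.data.to_numpy() == fps.data.to_numpy()).all()

    def test_unequal_fingerprint_lengths_rejected(self, tmp_path):
        (tmp_path / "f.tsv").write_text("compound\tbits\nc1\t101\nc2\t10\n")
        with pytest.raises(FormatError, match="unequal"):
            core_io.read_fingerprints(tmp_path / "f.tsv")


class TestLogNorm:
    def _counts(self, mat, labels=("A", "A", "B", "B")):
        mat = np.asarray(mat)
        samples = [f"S{i}" for i in range(mat.shape[1])]
        return CountMatrix(
            pd.DataFrame(mat, index=[f"G{i}" for i in range(mat.shape[0])],
                         columns=samples),
            pd.Series(list(labels[: mat.shape[1]]), index=samples),
        )

    def test_all_zero_gene_stays_zero(self):
        cm = self._counts([[0, 0, 0, 0], [10, 10, 10, 10], [5, 5, 5, 5]])
        expr = core_io.lognorm_counts(cm)
        assert np.allclose(expr.data.loc["G0"], 0.0)

    def test_hand_computed_logcpm(self):
        # library size 1e6, count 999,999 -> log2(1e6 * 999999/1e6 + 1) = log2(1e6)
        cm = self._counts([[999_999, 10, 10, 10], [1, 10, 10, 10]])
        expr = core_io.lognorm_counts(cm)
        assert expr.data.loc["G0", "S0"] == pytest.approx(np.log2(1_000_000), abs=1e-9)

    def test_cpm_scale_invariance(self):
        base = np.array([[10, 3, 8, 1], [5, 7, 2, 9], [1, 2, 3, 4]])
        doubled = base.copy()
        doubled[:, 0] *= 2
        a = core_io.lognorm_counts(self._counts(base))
        b = core_io.lognorm_counts(self._counts(doubled))
        assert np.allclose(a.data["S0"], b.data["S0"], atol=1e-12)

    def test_zero_library_rejected(self):
        cm = self._counts([[0, 1, 2, 2], [0, 1, 2, 2]])
        with pytest.raises(FormatError, match="S0"):
            core_io.lognorm_counts(cm)
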
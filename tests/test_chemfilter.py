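import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmtrepurpose import chemfilter
from gmtrepurpose.core_io import FingerprintSet, ScoreTable


def fps_of(rows: dict) -> FingerprintSet:
    return FingerprintSet(pd.DataFrame.from_dict(rows, orient="index"))


class TestTanimoto:
    def test_identical_fingerprints_score_one(self):
        assert chemfilter.tanimoto([1, 0, 1, 1], [1, 0, 1, 1]) == 1.0

    def test_disjoint_fingerprints_score_zero(self):
        assert chemfilter.tanimoto([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_hand_example_one_third(self):
        assert chemfilter.tanimoto([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            chemfilter.tanimoto([1, 0], [1, 0, 1])

    def test_empty_pair_defined_as_zero(self):
        assert chemfilter.tanimoto([0, 0], [0, 0]) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=4, max_size=16),
           st.lists(st.integers(0, 1), min_size=4, max_size=16))
    def test_symmetric_and_one_only_for_identical(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        s = chemfilter.tanimoto(a, b)
        assert s == chemfilter.tanimoto(b, a)
        if s == 1.0:
            assert a == b and any(a)


class TestSimilarityMatrix:
    def test_reference_member_flagged_similar(self):
        fps = fps_of({"c1": [1, 0, 1, 1], "c2": [0, 1, 0, 0]})
        refs = fps_of({"r1": [1, 0, 1, 1]})
        mat, flags = chemfilter.similarity_matrix(fps, refs)
        assert bool(flags["c1"]) and not bool(flags["c2"])
        assert mat.loc["c1", "r1"] == 1.0

    def test_just_below_threshold_not_flagged(self):
        fps = fps_of({"c1": [1] * 7 + [0, 0, 0]})
        refs = fps_of({"r1": [1] * 10})  # tanimoto 0.7 exactly with c1? 7/10
        _, flags = chemfilter.similarity_matrix(fps, refs, threshold=0.71)
        assert not bool(flags["c1"])

    def test_self_comparison_symmetric_unit_diagonal(self):
        fps = fps_of({"c1": [1, 0, 1], "c2": [0, 1, 1]})
        mat, _ = chemfilter.similarity_matrix(fps, fps)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)


class TestBbbFilter:
    def _table(self):
        return ScoreTable(pd.DataFrame(
            {"bbb_score_a": [80.0, 60.0, 40.0, 50.0],
             "bbb_score_b": [70.0, 20.0, 90.0, 50.0]},
            index=["good", "onlyA", "onlyB", "TMZ"]))

    def test_at_least_reference_rule(self):
        passed = chemfilter.bbb_filter(
            self._table(), ("bbb_score_a", "bbb_score_b"),
            mode="at_least_reference", reference_compound="TMZ")
        assert passed == {"good", "TMZ"}

    def test_top_k_requires_both_platforms(self):
        passed = chemfilter.bbb_filter(
            self._table(), ("bbb_score_a", "bbb_score_b"),
            mode="top_k_intersection", k=2)
        assert "good" in passed
        assert "onlyA" not in passed and "onlyB" not in passed

    def test_k_at_table_size_passes_everyone(self):
        passed = chemfilter.bbb_filter(
            self._table(), ("bbb_score_a", "bbb_score_b"),
            mode="top_k_intersection", k=4)
        assert len(passed) == 4

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            chemfilter.bbb_filter(self._table(), ("bbb_score_a", "bbb_score_b"),
                                  mode="at_least_reference", reference_compound="nope")


class TestPgpConsensus:
    def _calls(self, *rows):
        return ScoreTable(pd.DataFrame(
            list(rows), columns=["pgp_call_1", "pgp_call_2", "pgp_call_3"],
            index=[f"c{i}" for i in range(len(rows))]))

    def test_unanimous_non_substrate_passes(self):
        t = self._calls(["non-substrate"] * 3)
        assert chemfilter.pgp_consensus(t, list(t.data.columns)) == {"c0"}

    def test_single_substrate_call_fails(self):
        t = self._calls(["non-substrate", "non-substrate", "substrate"])
        assert chemfilter.pgp_consensus(t, list(t.data.columns)) == set()

    def test_unknown_category_rejected(self):
        t = ScoreTable(pd.DataFrame(
            [["non-substrate", "non-substrate", "non-substrate"]],
            columns=["pgp_call_1", "pgp_call_2", "pgp_call_3"], index=["c0"]))
        t.data.loc["c0", "pgp_call_2"] = "maybe"
        with pytest.raises(ValueError, match="category"):
            chemfilter.pgp_consensus(t, list(t.data.columns))


class TestCooccurrence:
    @pytest.mark.parametrize("kind, count, related",
                             [("gene", 4, True), ("gene", 3, False),
                              ("drug", 6, True), ("drug", 5, False)])
    def test_strict_thresholds(self, kind, count, related):
        t = ScoreTable(pd.DataFrame({"glioblastoma": [count]}, index=["x"]))
        flags = chemfilter.cooccurrence_filter(t, kind)
        assert bool(flags.loc["x", "glioblastoma"]) == related

    def test_negative_counts_rejected(self):
        t = ScoreTable(pd.DataFrame({"emt": [-1]}, index=["x"]))
        with pytest.raises(ValueError, match="negative"):
            chemfilter.cooccurrence_filter(t, "gene")


class TestFunnel:
    def _connectivity(self, taus):
        return pd.DataFrame({"summary_tau": list(taus.values()),
                             "pert_type": "compound"}, index=list(taus.keys()))

    def _fixture(self):
        # hand-enumerated truth: c1 passes everything; c2 fails BBB;
        # c3 fails tau; c4 fails P-gp; c5 missing from BBB table
        conn = self._connectivity({"c1": -95, "c2": -92, "c3": -50, "c4": -91, "c5": -99})
        bbb = ScoreTable(pd.DataFrame(
            {"bbb_score_a": [80, 10, 80, 80, 50], "bbb_score_b": [80, 80, 80, 80, 50]},
            index=["c1", "c2", "c3", "c4", "TMZ"]))
        pgp = ScoreTable(pd.DataFrame(
            [["non-substrate"] * 3, ["non-substrate"] * 3, ["non-substrate"] * 3,
             ["substrate", "non-substrate", "non-substrate"], ["non-substrate"] * 3],
            columns=["pgp_call_1", "pgp_call_2", "pgp_call_3"],
            index=["c1", "c2", "c3", "c4", "c5"]))
        cooc = ScoreTable(pd.DataFrame(
            {"glioblastoma": [10, 10, 10, 10, 10]},
            index=["c1", "c2", "c3", "c4", "c5"]))
        cfg = chemfilter.FunnelConfig(bbb_reference="TMZ")
        return conn, bbb, pgp, cooc, cfg

    def test_hand_enumerated_survivor_counts(self):
        conn, bbb, pgp, cooc, cfg = self._fixture()
        records, counts = chemfilter.run_funnel(conn, bbb, pgp, cooc, None, None, cfg)
        # tau <= -90: c1, c2, c4, c5 (4); BBB: c1, c4 (c2 fails, c5 unknown);
        # text keeps both; P-gp drops c4
        assert counts == {"cmap": 4, "bbb": 2, "text": 2, "pgp": 1, "similarity": 1}
        assert list(records.index[records["final_pass"]]) == ["c1"]
        assert records.loc["c5", "bbb_pass"] is None
        assert records["stage_reached"].to_dict() == {
            "c1": "similarity", "c2": "cmap", "c3": "none", "c4": "text", "c5": "cmap"}

    def test_counts_non_increasing_along_funnel(self):
        conn, bbb, pgp, cooc, cfg = self._fixture()
        _, counts = chemfilter.run_funnel(conn, bbb, pgp, cooc, None, None, cfg)
        vals = [counts[s] for s in chemfilter.FUNNEL_STAGES]
        assert vals == sorted(vals, reverse=True)

    def test_empty_connectivity_gives_zero_counts(self):
        conn = self._connectivity({})
        records, counts = chemfilter.run_funnel(conn, None, None, None, None, None)
        assert len(records) == 0
        assert all(v == 0 for v in counts.values())

    def test_permuted_stage_order_rejected(self):
        cfg = chemfilter.FunnelConfig(stage_order=("bbb", "cmap", "text", "pgp",
                                                   "similarity"))
        with pytest.raises(ValueError, match="fixed"):
            chemfilter.run_funnel(self._connectivity({"c1": -95}), None, None, None,
                                  None, None, cfg)
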
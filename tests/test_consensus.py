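"""Productivity filter and the >= 2-caller consensus rule."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrprofile import CallerTable, consensus_call, is_productive, productive_only
from tcrprofile.io import reverse_translate

from conftest import bclon, table


class TestIsProductive:
    def test_inframe_aa_is_productive(self):
        assert is_productive("CASSEGNYNSPLYF")

    def test_frame_violation_unproductive(self):
        assert not is_productive("A" * 40)  # nt, length not divisible by 3

    def test_stop_in_aa_unproductive(self):
        assert not is_productive("CASS*F")

    def test_stop_in_translation_unproductive(self):
        assert not is_productive(reverse_translate("CAS*F"))
        assert is_productive(reverse_translate("CASSF"))

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            is_productive("CASSX1")
        with pytest.raises(ValueError, match="empty"):
            is_productive("")

    def test_productive_only_filters_rows(self):
        t = table([(bclon(cdr3="CASSF"), 1.0), (bclon(cdr3="CAS*F"), 1.0)])
        assert len(productive_only(t).rows) == 1


def _tables(*vsets_by_caller, cdr3="CASSF", j="TRBJ1-1", support=10.0):
    """One table per caller, each holding one row for the same CDR3+J."""
    out = []
    for i, vset in enumerate(vsets_by_caller):
        rows = [] if vset is None else [(bclon(cdr3=cdr3, v=vset, j=j), support)]
        out.append(table(rows, caller_id=f"c{i}"))
    return out


class TestConsensusRule:
    def test_two_of_three_retained_one_of_three_dropped(self):
        shared = bclon(cdr3="CASSF")
        lone = bclon(cdr3="CARRF")
        tables = [
            table([(shared, 10.0), (lone, 5.0)], caller_id="a"),
            table([(shared, 20.0)], caller_id="b"),
            table([], caller_id="c"),
        ]
        result = consensus_call(tables, min_agree=2)
        assert {r.clonotype.cdr3_aa for r in result.rows} == {"CASSF"}
        (row,) = result.rows
        assert row.callers == frozenset({"a", "b"})
        assert row.support == pytest.approx(15.0)  # mean of agreeing callers

    def test_v_sets_intersected(self):
        result = consensus_call(_tables({"A", "B"}, {"B", "C"}), min_agree=2)
        (row,) = result.rows
        assert row.clonotype.v_genes == frozenset({"B"})

    def test_empty_v_intersection_is_not_a_match(self):
        result = consensus_call(_tables({"A"}, {"B"}), min_agree=2)
        assert result.rows == []

    def test_incompatible_caller_excluded_from_agreement(self):
        # two callers agree on A; the third's disjoint V does not veto them
        result = consensus_call(_tables({"A"}, {"A"}, {"B"}), min_agree=2)
        (row,) = result.rows
        assert row.clonotype.v_genes == frozenset({"A"})
        assert row.callers == frozenset({"c0", "c1"})

    def test_fewer_tables_than_min_agree_rejected(self):
        with pytest.raises(ValueError, match="min_agree"):
            consensus_call(_tables({"A"}), min_agree=2)

    def test_mixed_ambiguity_rows_keep_read_granularity(self):
        # 9 unambiguous reads + 1 read ambiguous between V and W, in both
        # callers: the ambiguous read must stay 1/N-weighted, not poison
        # the unambiguous majority.
        rows = [(bclon(cdr3="CASSF", v="TRBV1"), 9.0),
                (bclon(cdr3="CASSF", v={"TRBV1", "TRBV2"}), 1.0)]
        result = consensus_call([table(rows, caller_id="a"),
                                 table(rows, caller_id="b")], min_agree=2)
        by_v = {r.clonotype.v_genes: r.support for r in result.rows}
        assert by_v == {frozenset({"TRBV1"}): pytest.approx(9.0),
                        frozenset({"TRBV1", "TRBV2"}): pytest.approx(1.0)}


# -- property tests ---------------------------------------------------------

_VS = st.frozensets(st.sampled_from(["TRBV1", "TRBV2", "TRBV3"]), min_size=1)
_CDR3 = st.sampled_from(["CAAF", "CADF", "CAEF", "CAGF"])


@st.composite
def caller_tables(draw, k=3):
    tables = []
    for i in range(k):
        n = draw(st.integers(0, 4))
        seen = set()
        rows = []
        for _ in range(n):
            cdr3 = draw(_CDR3)
            vs = draw(_VS)
            if (cdr3, vs) in seen:
                continue
            seen.add((cdr3, vs))
            rows.append((bclon(cdr3=cdr3, v=vs), float(draw(st.integers(1, 50)))))
        tables.append(table(rows, caller_id=f"c{i}"))
    return tables


@settings(max_examples=200, deadline=None, derandomize=True)
@given(caller_tables())
def test_consensus_subset_and_v_containment(tables):
    """Consensus rows lie within the union of inputs on (CDR3, J) and each
    consensus V set is contained in every agreeing caller's V union."""
    result = consensus_call(tables, min_agree=2)
    union_keys = {r.clonotype.chain_key for t in tables for r in t.rows}
    by_caller = {t.caller_id: t for t in tables}
    for row in result.rows:
        assert row.clonotype.chain_key in union_keys
        for cid in row.callers:
            caller_vs = set().union(*(r.clonotype.v_genes
                                      for r in by_caller[cid].rows
                                      if r.clonotype.chain_key == row.clonotype.chain_key))
            assert row.clonotype.v_genes <= caller_vs


@settings(max_examples=200, deadline=None, derandomize=True)
@given(caller_tables())
def test_raising_min_agree_never_adds_rows(tables):
    keys2 = {r.clonotype.chain_key for r in consensus_call(tables, 2).rows}
    keys3 = {r.clonotype.chain_key for r in consensus_call(tables, 3).rows}
    assert keys3 <= keys2


@settings(max_examples=100, deadline=None, derandomize=True)
@given(caller_tables(k=1), st.integers(2, 4))
def test_consensus_of_identical_tables_is_identity(tables, k):
    """Consensus of k copies of one table reproduces its rows and supports."""
    (t,) = tables
    copies = [CallerTable(caller_id=f"c{i}", sample_id=t.sample_id, rows=t.rows)
              for i in range(k)]
    result = consensus_call(copies, min_agree=2)
    got = {(r.clonotype.chain_key, r.clonotype.v_genes): r.support
           for r in result.rows}
    want = {}
    for r in t.rows:
        key = (r.clonotype.chain_key, r.clonotype.v_genes)
        want[key] = want.get(key, 0.0) + r.read_count
    assert got.keys() == want.keys()
    for key in want:
        assert got[key] == pytest.approx(want[key])
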
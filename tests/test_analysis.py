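import io
import json

import pytest

from tpattern import (
    CriticalInterval,
    DetectionParams,
    EventType,
    PatternTemplate,
    TData,
    detect_tpatterns,
    event_type_inventory,
    export_pattern_diagram,
    export_pattern_table,
    pattern_stats,
    plant_pattern,
    select_patterns,
)
from tpattern.engine import PairNode, TPattern


def chain_pattern(labels, occs, p=0.001):
    """Left-leaning pattern over `labels` with flat occurrence tuples."""
    node = EventType.from_label(labels[0])
    for lab in labels[1:]:
        node = PairNode(
            left=node,
            right=EventType.from_label(lab),
            ci=CriticalInterval(0, 100, p, len(occs)),
        )

    def build(n, flat):
        if isinstance(n, EventType):
            return flat[0], flat[1:]
        left, rest = build(n.left, flat)
        right, rest = build(n.right, rest)
        return (left, right), rest

    return TPattern(structure=node, occurrences=[build(node, list(f))[0] for f in occs])


@pytest.fixture
def interaction_pattern():
    return chain_pattern(
        ["x,b,pick", "y,b,take", "x,e,look"],
        [(1, 5, 9), (20, 25, 29), (40, 44, 49), (60, 66, 69)],
    )


class TestPatternStats:
    def test_actor_switch_counting(self, interaction_pattern):
        st = pattern_stats(interaction_pattern)
        assert st.length == 3
        assert st.n == 4
        assert st.n_actors == 2
        assert st.actor_switches == 2

    def test_single_actor_no_switches(self):
        p = chain_pattern(["x,b,run", "x,e,run"], [(1, 5), (9, 14)])
        st = pattern_stats(p)
        assert st.n_actors == 1 and st.actor_switches == 0

    def test_span_statistics(self):
        p = chain_pattern(["A", "B"], [(5, 9), (20, 26)])
        st = pattern_stats(p)
        assert (st.min_span, st.max_span, st.mean_span) == (4, 6, 5.0)

    def test_levels_is_tree_depth(self, interaction_pattern):
        assert pattern_stats(interaction_pattern).levels == 2


class TestSelectPatterns:
    @pytest.fixture
    def pool(self):
        return [
            chain_pattern(["A", "B", "C"], [(1, 5, 9), (21, 25, 29)]),
            chain_pattern(["C", "B", "A"], [(1, 5, 9), (21, 25, 29)]),
            chain_pattern(["x,b,go", "y,b,go"], [(1, 5), (21, 25)]),
        ]

    def test_ordered_subsequence_filter(self, pool):
        kept = select_patterns(pool, ["A", "C"], ordered=True)
        assert [p.terminal_labels for p in kept] == [("A", "B", "C")]

    def test_unordered_multiset_filter(self, pool):
        kept = select_patterns(pool, ["A", "C"], ordered=False)
        assert len(kept) == 2

    def test_empty_required_is_identity(self, pool):
        assert select_patterns(pool, []) == pool

    def test_multi_actor_only(self, pool):
        kept = select_patterns(pool, multi_actor_only=True)
        assert [p.terminal_labels for p in kept] == [("x,b,go", "y,b,go")]

    def test_unknown_label_lists_known(self, pool):
        with pytest.raises(KeyError, match="unknown event-type"):
            select_patterns(pool, ["Z"])

    def test_filters_idempotent_and_commute(self, pool):
        once = select_patterns(pool, ["A"], ordered=True)
        twice = select_patterns(once, ["A"], ordered=True)
        assert once == twice
        ab = select_patterns(select_patterns(pool, ["A"]), ["B"])
        ba = select_patterns(select_patterns(pool, ["B"]), ["A"])
        assert ab == ba


class TestInventory:
    def test_first_appearance_levels(self):
        # ((A B) C): A and B are two levels below the root, C one
        p = chain_pattern(["A", "B", "C"], [(1, 5, 9), (21, 25, 29)])
        inv = {et.label: lvl for et, lvl in event_type_inventory([p])}
        assert inv == {"A": 2, "B": 2, "C": 1}

    def test_empty_list(self):
        assert event_type_inventory([]) == []

    def test_minimum_over_patterns(self):
        deep = chain_pattern(["A", "B", "C"], [(1, 5, 9)])
        shallow = chain_pattern(["X", "A"], [(1, 5)])
        inv = {et.label: lvl for et, lvl in event_type_inventory([deep, shallow])}
        assert inv["A"] == 1


class TestExports:
    def test_empty_table_is_header_only(self):
        buf = io.StringIO()
        export_pattern_table([], buf)
        lines = buf.getvalue().splitlines()
        assert len(lines) == 1 and lines[0].startswith("id\tpattern")

    def test_planted_fixture_row(self, planted_chain_fixture):
        data, truth = planted_chain_fixture
        patterns = detect_tpatterns(data, DetectionParams())
        buf = io.StringIO()
        export_pattern_table(patterns, buf)
        rows = [r.split("\t") for r in buf.getvalue().splitlines()[1:]]
        assert len(rows) == len(patterns)
        by_terminals = {r[2]: r for r in rows}
        assert any("A B C" in key for key in by_terminals)

    def test_re_export_byte_identical(self, interaction_pattern=None):
        p = chain_pattern(["A", "B"], [(5, 9), (20, 26), (40, 44)])
        one, two = io.StringIO(), io.StringIO()
        export_pattern_table([p], one)
        export_pattern_table([p], two)
        assert one.getvalue() == two.getvalue()

    def test_stats_recomputable_from_table(self):
        p = chain_pattern(
            ["x,b,pick", "y,b,take"], [(5, 9), (20, 26), (40, 44)]
        )
        buf = io.StringIO()
        export_pattern_table([p], buf)
        header, row = [r.split("\t") for r in buf.getvalue().splitlines()]
        rec = dict(zip(header, row))
        st = pattern_stats(p)
        assert int(rec["length"]) == st.length
        assert int(rec["n"]) == st.n
        assert int(rec["actors"]) == st.n_actors
        assert int(rec["switches"]) == st.actor_switches
        assert float(rec["mean_span"]) == pytest.approx(st.mean_span, rel=1e-5)


class TestDiagram:
    def test_dot_and_point_map(self, tmp_path):
        base = TData(T=10_000, series=[])
        data, _ = plant_pattern(base, PatternTemplate(("A", "B"), (5,), 4), seed=9)
        patterns = detect_tpatterns(data, DetectionParams())
        dot_path, json_path = export_pattern_diagram(
            patterns[0], data, tmp_path / "diag"
        )
        dot = dot_path.read_text()
        assert dot.startswith("digraph") and '"A"' in dot and '"B"' in dot
        pm = json.loads(json_path.read_text())
        assert pm["terminals"] == ["A", "B"]
        assert len(pm["occurrences"]) == 4

    def test_point_map_gaps_reverify_within_cis(self, tmp_path, planted_chain_fixture):
        data, truth = planted_chain_fixture
        patterns = detect_tpatterns(data, DetectionParams())
        _, json_path = export_pattern_diagram(patterns[0], data, tmp_path / "d")
        pm = json.loads(json_path.read_text())
        # terminal points of each exported occurrence are genuine series points
        for occ in pm["occurrences"]:
            for lab, t in zip(pm["terminals"], occ):
                assert t in pm["series"][lab]
        # gaps between consecutive terminals bounded by widest node interval
        dmax = max(node["d2"] for node in pm["nodes"])
        for occ in pm["occurrences"]:
            for a, b in zip(occ, occ[1:]):
                assert 0 <= b - a <= data.T and b - a <= dmax + max(
                    node["d2"] for node in pm["nodes"]
                ) * len(occ)

    def test_mismatched_data_rejected(self, tmp_path):
        p = chain_pattern(["A", "B"], [(5, 9)])
        from conftest import make_tdata

        with pytest.raises(KeyError, match="missing"):
            export_pattern_diagram(p, make_tdata(10, X=[1]), tmp_path / "x")
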
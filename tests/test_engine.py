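import numpy as np
import pytest

from tpattern import (
    CriticalInterval,
    DetectionParams,
    EventSeries,
    EventType,
    PatternTemplate,
    TData,
    WorkingSeries,
    completeness_competition,
    detect_tbursts,
    detect_tpatterns,
    find_recovered_pattern,
    generate_noise_tdata,
    pair_occurrences,
    plant_pattern,
    verify_pattern,
)
from tpattern.engine import PairNode, TPattern

from conftest import make_tdata
from oracle import detect_tpatterns_oracle


def ws(points):
    """Terminal-like working series from bare occurrence times."""
    return WorkingSeries(source=EventType("w"), occurrences=list(points))


class TestPairOccurrences:
    def test_unique_matches(self):
        ci = CriticalInterval(3, 6, 0.001, 2)
        pairs = pair_occurrences(ws([5, 20]), ws([9, 26]), ci)
        assert pairs == [(5, 9), (20, 26)]

    def test_earliest_left_wins_contention(self):
        ci = CriticalInterval(3, 4, 0.001, 1)
        pairs = pair_occurrences(ws([5, 6]), ws([9]), ci)
        assert pairs == [(5, 9)]

    def test_gap_outside_interval(self):
        ci = CriticalInterval(5, 6, 0.001, 1)
        assert pair_occurrences(ws([5]), ws([9]), ci) == []

    def test_each_right_used_once(self):
        ci = CriticalInterval(0, 100, 0.001, 3)
        pairs = pair_occurrences(ws([1, 2, 3]), ws([10]), ci)
        assert pairs == [(1, 10)]

    def test_no_pairing_across_sample_boundary(self):
        ci = CriticalInterval(1, 10, 0.001, 1)
        pairs = pair_occurrences(ws([9]), ws([12]), ci, boundaries=[10, 20])
        assert pairs == []

    def test_shared_underlying_point_rejected(self):
        # the same 'w' point cannot serve both sides of one pair
        ci = CriticalInterval(0, 0, 0.001, 1)
        pairs = pair_occurrences(ws([5]), ws([5]), ci)
        assert pairs == []


class TestDetectTPatterns:
    def test_planted_pair_in_silence(self):
        base = TData(T=10_000, series=[])
        data, truth = plant_pattern(
            base, PatternTemplate(("A", "B"), (5,), 6), seed=2
        )
        patterns = detect_tpatterns(data, DetectionParams())
        assert len(patterns) == 1
        p = patterns[0]
        assert p.terminal_labels == ("A", "B")
        node = p.structure
        assert (node.ci.d1, node.ci.d2) == (5, 5)
        assert p.n == 6
        assert p.flat_occurrences() == truth

    def test_planted_three_terminal_recovered(self, planted_chain_fixture):
        data, truth = planted_chain_fixture
        patterns = detect_tpatterns(data, DetectionParams())
        hit = find_recovered_pattern(patterns, ("A", "B", "C"), truth)
        assert hit is not None
        assert hit.n >= 4

    def test_empty_tdata_gives_empty_result(self):
        assert detect_tpatterns(TData(T=10, series=[]), DetectionParams()) == []

    def test_determinism(self, planted_chain_fixture):
        data, _ = planted_chain_fixture
        a = detect_tpatterns(data, DetectionParams())
        b = detect_tpatterns(data, DetectionParams())
        assert [p.signature() for p in a] == [p.signature() for p in b]

    def test_every_pattern_reverifies(self, planted_chain_fixture):
        data, _ = planted_chain_fixture
        params = DetectionParams()
        for p in detect_tpatterns(data, params):
            verify_pattern(p, data, params)

    def test_noise_patterns_reverify_too(self):
        data = generate_noise_tdata(6, 20, 10_000, seed=532)
        params = DetectionParams()
        for p in detect_tpatterns(data, params):
            verify_pattern(p, data, params)

    def test_monotonicity_in_alpha_and_n_min(self):
        """On a clean planted fixture, loosening thresholds only adds."""
        base = TData(T=10_000, series=[])
        data, _ = plant_pattern(base, PatternTemplate(("A", "B"), (5,), 6), seed=2)
        strict = {p.signature() for p in detect_tpatterns(data, DetectionParams(alpha=0.001, n_min=4))}
        loose = {p.signature() for p in detect_tpatterns(data, DetectionParams(alpha=0.01, n_min=3))}
        assert strict <= loose

    def test_results_sorted_by_length_then_p(self, planted_chain_fixture):
        data, _ = planted_chain_fixture
        patterns = detect_tpatterns(data, DetectionParams())
        key = [(-p.m, p.max_p) for p in patterns]
        assert key == sorted(key)

    def test_max_length_cap_respected(self, planted_chain_fixture):
        data, _ = planted_chain_fixture
        patterns = detect_tpatterns(data, DetectionParams(max_length=2))
        assert all(p.m <= 2 for p in patterns)


class TestOracleEquivalence:
    """Brute-force re-implementation agrees with the engine on
    micro-instances (<= 3 series, <= 8 points, T <= 60)."""

    @pytest.mark.parametrize("seed", range(10))
    def test_random_micro_instances(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(25, 61))
        labels = ["a", "b", "c"][: int(rng.integers(2, 4))]
        series = []
        for lab in labels:
            k = int(rng.integers(2, 9))
            pts = sorted(int(x) for x in rng.choice(T, k, replace=False) + 1)
            series.append(EventSeries(EventType(lab), pts))
        data = TData(T=T, series=series)
        params = DetectionParams(alpha=0.05, n_min=2, max_length=4, max_levels=4)
        got = {p.signature() for p in detect_tpatterns(data, params)}
        expected = detect_tpatterns_oracle(data, params)
        assert got == expected

    def test_planted_micro_instance(self):
        data = make_tdata(60, a=[3, 20, 41], b=[7, 24, 45])
        params = DetectionParams(alpha=0.05, n_min=3, max_length=4, max_levels=4)
        got = {p.signature() for p in detect_tpatterns(data, params)}
        expected = detect_tpatterns_oracle(data, params)
        assert got == expected
        assert got  # the planted (a b) gap-4 pair is found by both


class TestCompletenessCompetition:
    def _pattern(self, labels, occs, p=0.001):
        node = EventType(labels[0])
        for lab in labels[1:]:
            node = PairNode(left=node, right=EventType(lab), ci=CriticalInterval(0, 100, p, len(occs)))

        def build(n, flat):
            if isinstance(n, EventType):
                return flat[0], flat[1:]
            left, rest = build(n.left, flat)
            right, rest = build(n.right, rest)
            return (left, right), rest

        occ_trees = [build(node, list(f))[0] for f in occs]
        return TPattern(structure=node, occurrences=occ_trees)

    def test_contained_equal_count_dropped(self):
        q = self._pattern(["A", "B", "C"], [(1, 5, 9), (20, 25, 29), (40, 44, 49), (60, 66, 69)])
        p = self._pattern(["A", "B"], [(1, 5), (20, 25), (40, 44), (60, 66)])
        survivors = completeness_competition([p, q])
        assert survivors == [q]

    def test_extra_instances_keep_both(self):
        q = self._pattern(["A", "B", "C"], [(1, 5, 9), (20, 25, 29)])
        p = self._pattern(
            ["A", "B"], [(1, 5), (20, 25), (40, 44), (60, 66), (70, 75), (80, 85), (90, 95)]
        )
        survivors = completeness_competition([p, q])
        assert set(map(id, survivors)) == {id(p), id(q)}

    def test_same_points_needed_not_just_overlap(self):
        # Q covers P's spans but uses different B points: P survives
        q = self._pattern(["A", "B", "C"], [(1, 6, 9), (20, 26, 29)])
        p = self._pattern(["A", "B"], [(1, 5), (20, 25)])
        survivors = completeness_competition([p, q])
        assert len(survivors) == 2

    def test_tree_shape_dedup_keeps_smaller_max_p(self):
        flat = [(1, 5, 9), (20, 25, 29)]
        left_heavy = self._pattern(["A", "B", "C"], flat, p=0.004)
        right_heavy = TPattern(
            structure=PairNode(
                left=EventType("A"),
                right=PairNode(
                    left=EventType("B"),
                    right=EventType("C"),
                    ci=CriticalInterval(0, 100, 0.0005, 2),
                ),
                ci=CriticalInterval(0, 100, 0.001, 2),
            ),
            occurrences=[(1, (5, 9)), (20, (25, 29))],
        )
        survivors = completeness_competition([left_heavy, right_heavy])
        assert survivors == [right_heavy]


class TestBursts:
    def test_two_planted_runs(self):
        data = make_tdata(10_000, u=[10, 11, 12, 500, 800, 801, 803])
        bursts = detect_tbursts(data.series[0], data, DetectionParams(mode="burst"))
        assert len(bursts) == 1
        assert bursts[0].spans == [(10, 12), (800, 803)]
        assert bursts[0].structure.ci.d1 == 0

    def test_single_tight_pair_in_long_period(self):
        data = make_tdata(10**6, u=[5, 6])
        bursts = detect_tbursts(data.series[0], data, DetectionParams(mode="burst"))
        assert [b.spans for b in bursts] == [[(5, 6)]]

    def test_uniform_series_rejected(self):
        fp = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            pts = sorted(int(x) for x in rng.choice(10_000, 20, replace=False) + 1)
            data = make_tdata(10_000, u=pts)
            fp += bool(detect_tbursts(data.series[0], data, DetectionParams(mode="burst")))
        assert fp <= 1

    def test_short_series_empty(self):
        data = make_tdata(100, u=[5])
        assert detect_tbursts(data.series[0], data, DetectionParams(mode="burst")) == []

    def test_runs_never_cross_sample_boundary(self):
        from tpattern import concatenate_samples

        s1 = make_tdata(20, u=[18, 19, 20])
        s2 = make_tdata(20, u=[1, 2, 3])
        data = concatenate_samples([s1, s2])
        bursts = detect_tbursts(data.get_series("u"), data, DetectionParams(mode="burst"))
        for b in bursts:
            for start, end in b.spans:
                assert data.sample_index(start) == data.sample_index(end)

    def test_burst_mode_detection_includes_bursts(self):
        data = make_tdata(10_000, u=[10, 11, 12, 500, 800, 801, 803])
        patterns = detect_tpatterns(data, DetectionParams(mode="burst"))
        assert any(p.is_burst for p in patterns)
        for p in patterns:
            verify_pattern(p, data, DetectionParams(mode="burst"))
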
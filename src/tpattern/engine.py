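"""Bottom-up binary-tree T-pattern construction.

A T-pattern ``Q: X1 [d1,d2]1 X2 ... Xm`` is an ordered set of components
recurring such that each consecutive distance falls within a
component-pair-specific critical interval significantly more often than
expected under independent random placement. Detection is bottom-up:
starting from the raw event series, every ordered pair of working series
is tested for a critical interval relating the left part's end-points to
the right part's start-points; significant pairs become new patterns whose
occurrence series joins the continued search, so pairs of pairs (and so
on) assemble a binary construction tree. After each pass a *completeness
competition* discards redundant partial detections of the same underlying
pattern.

T-bursts — univariate patterns with a fast interval ``[0, d2]``, i.e.
significant dense runs within a single series — are detected by the same
critical-interval test of a series against itself and may nest inside
larger patterns.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence, Union

from .ci_stats import CriticalInterval, DetectionParams, detect_critical_interval
from .tdata import EventSeries, EventType, TData

__all__ = [
    "PairNode",
    "BurstNode",
    "TPattern",
    "WorkingSeries",
    "pair_occurrences",
    "detect_tpatterns",
    "detect_tbursts",
    "completeness_competition",
    "verify_pattern",
    "PatternVerificationError",
]


@dataclass(frozen=True)
class PairNode:
    """Internal tree node: left part followed by right part within a CI."""

    left: "Node"
    right: "Node"
    ci: CriticalInterval


@dataclass(frozen=True)
class BurstNode:
    """Univariate fast-interval node: dense runs within one series."""

    event_type: EventType
    ci: CriticalInterval


Node = Union[EventType, PairNode, BurstNode]

# An occurrence mirrors the tree: an int at a terminal, a (left, right)
# tuple at a PairNode, and a tuple of run times at a BurstNode.
Occurrence = Union[int, tuple]


def _node_terminals(node: Node) -> list[EventType]:
    if isinstance(node, EventType):
        return [node]
    if isinstance(node, BurstNode):
        return [node.event_type]
    return _node_terminals(node.left) + _node_terminals(node.right)


def _node_depth(node: Node) -> int:
    if isinstance(node, (EventType, BurstNode)):
        return 0
    return 1 + max(_node_depth(node.left), _node_depth(node.right))


def _node_signature(node: Node) -> tuple:
    if isinstance(node, EventType):
        return ("t", node.label)
    if isinstance(node, BurstNode):
        return ("b", node.event_type.label, node.ci.d1, node.ci.d2)
    return (
        "p",
        _node_signature(node.left),
        _node_signature(node.right),
        node.ci.d1,
        node.ci.d2,
    )


def _node_max_p(node: Node) -> float:
    if isinstance(node, EventType):
        return 0.0
    if isinstance(node, BurstNode):
        return node.ci.p_value
    return max(node.ci.p_value, _node_max_p(node.left), _node_max_p(node.right))


def flatten_occurrence(node: Node, occ: Occurrence) -> list[int]:
    """Terminal times of one occurrence, in pattern order."""
    if isinstance(node, EventType):
        return [occ]
    if isinstance(node, BurstNode):
        return list(occ)
    return flatten_occurrence(node.left, occ[0]) + flatten_occurrence(
        node.right, occ[1]
    )


def labeled_points(node: Node, occ: Occurrence) -> frozenset[tuple[str, int]]:
    """The underlying (series label, time) points of one occurrence."""
    if isinstance(node, EventType):
        return frozenset({(node.label, occ)})
    if isinstance(node, BurstNode):
        return frozenset((node.event_type.label, t) for t in occ)
    return labeled_points(node.left, occ[0]) | labeled_points(node.right, occ[1])


@dataclass
class TPattern:
    """A detected pattern: a binary tree plus its dated occurrences.

    Treated as immutable after construction (derived views are cached).
    """

    structure: Node
    occurrences: list

    @property
    def m(self) -> int:
        """Length: number of terminal components (bursts count once)."""
        return len(self.terminals)

    @property
    def terminals(self) -> list[EventType]:
        cached = self.__dict__.get("_terminals")
        if cached is None:
            cached = _node_terminals(self.structure)
            self.__dict__["_terminals"] = cached
        return cached

    @property
    def terminal_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terminals)

    @property
    def level(self) -> int:
        """Depth of the binary construction tree (a pair of terminals: 1)."""
        return _node_depth(self.structure)

    @property
    def n(self) -> int:
        return len(self.occurrences)

    @property
    def is_burst(self) -> bool:
        return isinstance(self.structure, BurstNode)

    def flat_occurrences(self) -> list[tuple[int, ...]]:
        cached = self.__dict__.get("_flat")
        if cached is None:
            cached = [
                tuple(flatten_occurrence(self.structure, o)) for o in self.occurrences
            ]
            self.__dict__["_flat"] = cached
        return cached

    @property
    def spans(self) -> list[tuple[int, int]]:
        return [(f[0], f[-1]) for f in self.flat_occurrences()]

    @property
    def max_p(self) -> float:
        """Largest p-value over the pattern's internal nodes."""
        return _node_max_p(self.structure)

    def signature(self) -> tuple:
        cached = self.__dict__.get("_sig")
        if cached is None:
            cached = (
                _node_signature(self.structure),
                tuple(self.flat_occurrences()),
            )
            self.__dict__["_sig"] = cached
        return cached

    def nodes(self) -> list[Node]:
        """All internal nodes, root first."""
        out: list[Node] = []

        def walk(n: Node) -> None:
            if isinstance(n, (PairNode, BurstNode)):
                out.append(n)
            if isinstance(n, PairNode):
                walk(n.left)
                walk(n.right)

        walk(self.structure)
        return out

    def label(self) -> str:
        """Human-readable structure string, e.g. ``((a b) c)``."""

        def fmt(n: Node) -> str:
            if isinstance(n, EventType):
                return n.label
            if isinstance(n, BurstNode):
                return f"burst({n.event_type.label})"
            return f"({fmt(n.left)} {fmt(n.right)})"

        return fmt(self.structure)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TPattern({self.label()}, n={self.n})"


@dataclass
class WorkingSeries:
    """A terminal event-type or a built pattern with its occurrence series."""

    source: EventType | TPattern
    occurrences: list

    @property
    def node(self) -> Node:
        if isinstance(self.source, EventType):
            return self.source
        return self.source.structure

    @property
    def m(self) -> int:
        if isinstance(self.source, EventType):
            return 1
        return self.source.m

    def spans(self) -> list[tuple[int, int]]:
        node = self.node
        out = []
        for o in self.occurrences:
            f = flatten_occurrence(node, o)
            out.append((f[0], f[-1]))
        return out

    @classmethod
    def from_series(cls, series: EventSeries) -> "WorkingSeries":
        return cls(source=series.event_type, occurrences=list(series.points))

    @classmethod
    def from_pattern(cls, pattern: TPattern) -> "WorkingSeries":
        return cls(source=pattern, occurrences=list(pattern.occurrences))


# ---------------------------------------------------------------------------
# Occurrence pairing


def pair_occurrences(
    left: WorkingSeries,
    right: WorkingSeries,
    ci: CriticalInterval,
    boundaries: Sequence[int] | None = None,
) -> list[tuple]:
    """Greedy earliest matching of left and right occurrences under a CI.

    Left occurrences are scanned in start order; each is joined to the
    earliest unused right occurrence whose start ``s`` satisfies
    ``d1 <= s - e <= d2`` (``e`` = left end) within the same sample. Each
    occurrence is used at most once, and the two sides of a pair must not
    share any underlying point (a component occurrence cannot double as
    part of its own context). Returns paired occurrence trees
    ``(left_occ, right_occ)`` sorted by combined start.
    """
    lnode, rnode = left.node, right.node
    lefts = sorted(
        ((flatten_occurrence(lnode, o), o) for o in left.occurrences),
        key=lambda x: x[0][0],
    )
    rights = sorted(
        ((flatten_occurrence(rnode, o), o) for o in right.occurrences),
        key=lambda x: x[0][0],
    )
    rpoints = [labeled_points(rnode, o) for _, o in rights]
    used = [False] * len(rights)
    pairs: list[tuple] = []

    def sample_of(t: int) -> int:
        if boundaries is None:
            return 0
        return bisect_left(boundaries, t)

    for lflat, locc in lefts:
        e = lflat[-1]
        lpoints = None
        for j, (rflat, rocc) in enumerate(rights):
            if used[j]:
                continue
            gap = rflat[0] - e
            if gap > ci.d2:
                break  # rights sorted by start; no later one can fit
            if gap >= ci.d1 and sample_of(e) == sample_of(rflat[0]):
                if lpoints is None:
                    lpoints = labeled_points(lnode, locc)
                if lpoints & rpoints[j]:
                    continue
                used[j] = True
                pairs.append((locc, rocc))
                break
    pairs.sort(key=lambda p: flatten_occurrence(lnode, p[0])[0])
    return pairs


# ---------------------------------------------------------------------------
# Completeness competition


def _is_subsequence(short: Sequence[str], long: Sequence[str]) -> bool:
    it = iter(long)
    return all(any(x == y for y in it) for x in short)


def _occ_points(pattern: TPattern) -> list[tuple[tuple[str, int], ...]]:
    """Each occurrence as its ordered (label, time) terminal points."""
    if pattern.is_burst:
        lab = pattern.terminals[0].label
        return [tuple((lab, t) for t in f) for f in pattern.flat_occurrences()]
    labels = pattern.terminal_labels
    return [tuple(zip(labels, f)) for f in pattern.flat_occurrences()]


def _points_subsequence(
    inner: tuple[tuple[str, int], ...], outer: tuple[tuple[str, int], ...]
) -> bool:
    it = iter(outer)
    return all(any(x == y for y in it) for x in inner)


def _occurrences_contained(p: TPattern, q: TPattern) -> bool:
    """Every occurrence of P realized inside a distinct occurrence of Q,
    point for point (greedy matching in start order)."""
    p_occs = _occ_points(p)
    q_occs = _occ_points(q)
    used = [False] * len(q_occs)
    for po in p_occs:
        for j, qo in enumerate(q_occs):
            if not used[j] and _points_subsequence(po, qo):
                used[j] = True
                break
        else:
            return False
    return True


def completeness_competition(candidates: list[TPattern]) -> list[TPattern]:
    """Discard redundant detections of the same underlying pattern.

    Two rules, applied in order:

    1. Among patterns with identical terminal sequence and identical
       occurrence times but different tree shapes, keep the one whose
       maximal node p-value is smallest (tie: first constructed).
    2. Drop P when some Q exists such that P's terminal sequence is an
       ordered subsequence of Q's, both have equally many occurrences,
       and every occurrence of P occurs exactly inside a distinct
       occurrence of Q — the same terminal points, so P is a less
       complete detection of the same underlying pattern.
    """
    # rule 1: dedupe tree shapes over identical content
    best: dict[tuple, TPattern] = {}
    order: list[tuple] = []
    for p in candidates:
        key = (p.terminal_labels, tuple(p.flat_occurrences()))
        if key not in best:
            best[key] = p
            order.append(key)
        elif p.max_p < best[key].max_p:
            best[key] = p
    pool = [best[k] for k in order]

    # rule 2: containment drop
    survivors: list[TPattern] = []
    for p in pool:
        redundant = False
        for q in pool:
            if q is p:
                continue
            if (
                len(q.terminal_labels) > len(p.terminal_labels)
                and q.n == p.n
                and _is_subsequence(p.terminal_labels, q.terminal_labels)
                and _occurrences_contained(p, q)
            ):
                redundant = True
                break
        if not redundant:
            survivors.append(p)
    return survivors


# ---------------------------------------------------------------------------
# Burst detection


def detect_tbursts(
    series: EventSeries, data: TData, params: DetectionParams
) -> list[TPattern]:
    """Detect T-bursts: significant dense runs within a single series.

    The series is tested against itself over fast intervals ``[0, d2]``
    with ``d2`` drawn from the observed successive-point gaps. If a
    significant interval is found, burst instances are the maximal runs
    of at least two consecutive points with same-sample gaps <= d2.
    """
    pts = series.points
    if len(pts) < 2:
        return []
    burst_params = params.with_mode("burst")
    ci = detect_critical_interval(
        pts, pts, data.T, burst_params, data.sample_boundaries
    )
    if ci is None:
        return []
    runs: list[tuple[int, ...]] = []
    run = [pts[0]]
    for a, b in zip(pts, pts[1:]):
        same = data.sample_index(a) == data.sample_index(b)
        if same and b - a <= ci.d2:
            run.append(b)
        else:
            if len(run) >= 2:
                runs.append(tuple(run))
            run = [b]
    if len(run) >= 2:
        runs.append(tuple(run))
    if not runs:
        return []
    node = BurstNode(event_type=series.event_type, ci=ci)
    return [TPattern(structure=node, occurrences=runs)]


# ---------------------------------------------------------------------------
# Main detection loop


def _starts(ws: WorkingSeries) -> list[int]:
    return sorted({s for s, _ in ws.spans()})


def _ends(ws: WorkingSeries) -> list[int]:
    return sorted({e for _, e in ws.spans()})


def detect_tpatterns(data: TData, params: DetectionParams) -> list[TPattern]:
    """Bottom-up T-pattern search over a TData.

    Each pass tests every ordered pair of distinct working series
    (terminal event-types and previously built patterns) for a critical
    interval relating the left part's end-points to the right part's
    start-points; significant pairs with at least ``n_min`` paired
    occurrences become candidate patterns. After each pass the
    completeness competition prunes redundant candidates and survivors
    join the working set. The loop stops at a fixpoint or after
    ``max_levels`` passes.

    In mode ``fixed_11`` only the interval ``[1, 1]`` is tested (string /
    sequence analysis); in mode ``burst``, per-series T-bursts are
    detected first and join the working set so they can nest inside
    larger patterns.

    Returns surviving patterns sorted by length (descending) then
    maximal node p-value (ascending).
    """
    boundaries = data.sample_boundaries
    terminals = [
        WorkingSeries.from_series(s) for s in data.series if len(s.points) > 0
    ]
    patterns: list[TPattern] = []
    if params.mode == "burst":
        for s in data.series:
            patterns.extend(detect_tbursts(s, data, params))

    pair_mode = "fixed_11" if params.mode == "fixed_11" else "general"
    pair_params = params.with_mode(pair_mode)

    built: set[tuple] = {p.signature() for p in patterns}
    memo: dict[tuple, TPattern | None] = {}

    def ws_key(ws: WorkingSeries) -> tuple:
        if isinstance(ws.source, EventType):
            return ("t", ws.source.label)
        return ws.source.signature()

    for _ in range(params.max_levels):
        working = terminals + [WorkingSeries.from_pattern(p) for p in patterns]
        new_candidates: list[TPattern] = []
        for P in working:
            for Q in working:
                if P is Q or P.m + Q.m > params.max_length:
                    continue
                key = (ws_key(P), ws_key(Q))
                if key in memo:
                    cand = memo[key]
                else:
                    cand = _build_candidate(P, Q, data, pair_params, boundaries)
                    memo[key] = cand
                if cand is not None and cand.signature() not in built:
                    built.add(cand.signature())
                    new_candidates.append(cand)
        if not new_candidates:
            break
        survivors = completeness_competition(patterns + new_candidates)
        if {p.signature() for p in survivors} == {p.signature() for p in patterns}:
            break
        patterns = survivors

    patterns.sort(
        key=lambda p: (-p.m, p.max_p, p.terminal_labels, p.spans[0] if p.spans else (0, 0))
    )
    return patterns


def _build_candidate(
    P: WorkingSeries,
    Q: WorkingSeries,
    data: TData,
    pair_params: DetectionParams,
    boundaries: Sequence[int],
) -> TPattern | None:
    a_pts = _ends(P)
    b_pts = _starts(Q)
    ci = detect_critical_interval(a_pts, b_pts, data.T, pair_params, boundaries)
    if ci is None:
        return None
    occs = pair_occurrences(P, Q, ci, boundaries)
    if len(occs) < pair_params.n_min:
        return None
    node = PairNode(left=P.node, right=Q.node, ci=ci)
    return TPattern(structure=node, occurrences=occs)


# ---------------------------------------------------------------------------
# Independent verification


class PatternVerificationError(AssertionError):
    """A reported pattern failed re-verification against raw T-data."""


def verify_pattern(
    pattern: TPattern, data: TData, params: DetectionParams
) -> None:
    """Re-check all pattern invariants from raw T-data.

    Checks, without trusting the builder: every terminal time is a point
    of the corresponding event series; occurrences are sorted by start,
    lie within one sample each, and reuse no terminal point; every
    internal node's realized gaps lie within its critical interval, whose
    stored p-value is within the significance level; composite patterns
    recur at least ``n_min`` times. Raises
    :class:`PatternVerificationError` on any violation.
    """
    node = pattern.structure
    flats = pattern.flat_occurrences()
    terms = pattern.terminals
    if not pattern.is_burst:
        if pattern.m < 2:
            raise PatternVerificationError("composite pattern with m < 2")
        if pattern.n < params.n_min:
            raise PatternVerificationError(
                f"{pattern.label()}: n={pattern.n} below n_min={params.n_min}"
            )
    series = {s.label: set(s.points) for s in data.series}
    used: set[tuple[str, int, int]] = set()
    prev_start = None
    for occ, flat in zip(pattern.occurrences, flats):
        if prev_start is not None and flat[0] < prev_start:
            raise PatternVerificationError("occurrences not sorted by start")
        prev_start = flat[0]
        if data.sample_index(flat[0]) != data.sample_index(flat[-1]):
            raise PatternVerificationError("occurrence crosses a sample boundary")
        if pattern.is_burst:
            labels = [terms[0].label] * len(flat)
        else:
            labels = [t.label for t in terms]
        within: set[tuple[str, int]] = set()
        for pos, (lab, t) in enumerate(zip(labels, flat)):
            if lab not in series or t not in series[lab]:
                raise PatternVerificationError(
                    f"terminal time {t} not in series {lab!r}"
                )
            if (lab, t) in within:
                raise PatternVerificationError(
                    f"terminal point ({lab!r}, t={t}) reused within one occurrence"
                )
            within.add((lab, t))
            key = (lab, pos, t)
            if key in used:
                raise PatternVerificationError(
                    f"terminal point ({lab!r}, t={t}) reused across occurrences"
                )
            used.add(key)
        _verify_node_gaps(node, occ, params)


def _verify_node_gaps(node: Node, occ: Occurrence, params: DetectionParams) -> None:
    if isinstance(node, EventType):
        return
    if node.ci.p_value > params.alpha:
        raise PatternVerificationError(
            f"node p={node.ci.p_value} exceeds alpha={params.alpha}"
        )
    if isinstance(node, BurstNode):
        if len(occ) < 2:
            raise PatternVerificationError("burst run shorter than 2 points")
        for a, b in zip(occ, occ[1:]):
            if not (0 <= b - a <= node.ci.d2):
                raise PatternVerificationError(
                    f"burst gap {b - a} outside [0, {node.ci.d2}]"
                )
        return
    left_flat = flatten_occurrence(node.left, occ[0])
    right_flat = flatten_occurrence(node.right, occ[1])
    gap = right_flat[0] - left_flat[-1]
    if not (node.ci.d1 <= gap <= node.ci.d2):
        raise PatternVerificationError(
            f"gap {gap} outside CI [{node.ci.d1}, {node.ci.d2}]"
        )
    _verify_node_gaps(node.left, occ[0], params)
    _verify_node_gaps(node.right, occ[1], params)
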
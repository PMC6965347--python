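"""Qualitative and quantitative analysis of detected T-patterns.

Per-pattern statistics (length, levels, occurrences, actors and switches
between them), selection filters over the detected set, the behavior
inventory with first-appearance levels, and static table/diagram export
for downstream statistics or inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .engine import BurstNode, EventType, Node, TPattern
from .tdata import TData

__all__ = [
    "PatternStats",
    "pattern_stats",
    "select_patterns",
    "event_type_inventory",
    "export_pattern_table",
    "export_pattern_diagram",
    "pattern_to_dot",
    "pattern_point_map",
]


@dataclass(frozen=True)
class PatternStats:
    """Summary statistics of one detected pattern."""

    length: int
    levels: int
    n: int
    n_actors: int
    actor_switches: int
    min_span: int
    max_span: int
    mean_span: float


def pattern_stats(p: TPattern) -> PatternStats:
    """Compute length, level, occurrence, actor and span statistics.

    Actor counts rely on the ``actor,phase,behavior`` label convention;
    terminals without a parsed actor are excluded from actor statistics.
    A switch is an adjacent pair of actor-bearing terminals with
    different actors.
    """
    actors = [t.actor for t in p.terminals if t.actor]
    switches = sum(1 for a, b in zip(actors, actors[1:]) if a != b)
    spans = [e - s for s, e in p.spans]
    return PatternStats(
        length=p.m,
        levels=p.level,
        n=p.n,
        n_actors=len(set(actors)),
        actor_switches=switches,
        min_span=min(spans),
        max_span=max(spans),
        mean_span=sum(spans) / len(spans),
    )


def _labels_of(required: Sequence[EventType | str]) -> list[str]:
    return [r.label if isinstance(r, EventType) else r for r in required]


def _is_subsequence(short: Sequence[str], long: Sequence[str]) -> bool:
    it = iter(long)
    return all(any(x == y for y in it) for x in short)


def _multiset_contains(seq: Sequence[str], required: Sequence[str]) -> bool:
    pool = list(seq)
    for r in required:
        if r in pool:
            pool.remove(r)
        else:
            return False
    return True


def select_patterns(
    patterns: list[TPattern],
    required: Sequence[EventType | str] = (),
    ordered: bool = False,
    multi_actor_only: bool = False,
) -> list[TPattern]:
    """Filter patterns by included event-types, order, and actor count.

    Keeps patterns whose terminal sequence contains all ``required``
    event-types — as an ordered subsequence when ``ordered``, as a
    multiset otherwise. ``multi_actor_only`` additionally requires at
    least two distinct actors (interaction patterns). Unknown required
    labels raise a ``KeyError`` listing the known ones. Filters are
    idempotent and commute.
    """
    req = _labels_of(required)
    known = sorted({lab for p in patterns for lab in p.terminal_labels})
    unknown = sorted(set(req) - set(known))
    if unknown:
        raise KeyError(
            f"unknown event-type(s) {unknown}; known event-types: {known}"
        )
    out = []
    for p in patterns:
        labels = list(p.terminal_labels)
        if ordered:
            if not _is_subsequence(req, labels):
                continue
        elif not _multiset_contains(labels, req):
            continue
        if multi_actor_only:
            if len({t.actor for t in p.terminals if t.actor}) < 2:
                continue
        out.append(p)
    return out


def _terminal_depths(node: Node, depth: int = 0) -> list[tuple[EventType, int]]:
    if isinstance(node, EventType):
        return [(node, depth)]
    if isinstance(node, BurstNode):
        return [(node.event_type, depth)]
    return _terminal_depths(node.left, depth + 1) + _terminal_depths(
        node.right, depth + 1
    )


def event_type_inventory(
    patterns: Iterable[TPattern],
) -> list[tuple[EventType, int]]:
    """Event-types occurring in any pattern, with the minimum tree level
    (depth below the root) at which each first appears as a terminal.

    Sorted by label; an empty pattern list yields an empty inventory.
    """
    first: dict[str, tuple[EventType, int]] = {}
    for p in patterns:
        for et, depth in _terminal_depths(p.structure):
            cur = first.get(et.label)
            if cur is None or depth < cur[1]:
                first[et.label] = (et, depth)
    return [first[lab] for lab in sorted(first)]


# ---------------------------------------------------------------------------
# Export

_TABLE_COLUMNS = [
    "id",
    "pattern",
    "terminals",
    "length",
    "levels",
    "n",
    "actors",
    "switches",
    "min_span",
    "max_span",
    "mean_span",
    "critical_intervals",
]


def export_pattern_table(patterns: list[TPattern], target: TextIO) -> None:
    """Write one TSV row per pattern with stable column order.

    ``critical_intervals`` lists each internal node root-first as
    ``d1:d2:p``. Re-exporting the same patterns is byte-identical.
    """
    target.write("\t".join(_TABLE_COLUMNS) + "\n")
    for i, p in enumerate(patterns):
        st = pattern_stats(p)
        cis = ";".join(
            f"{n.ci.d1}:{n.ci.d2}:{n.ci.p_value:.6g}" for n in p.nodes()
        )
        row = [
            str(i),
            p.label(),
            " ".join(p.terminal_labels),
            str(st.length),
            str(st.levels),
            str(st.n),
            str(st.n_actors),
            str(st.actor_switches),
            str(st.min_span),
            str(st.max_span),
            f"{st.mean_span:.6g}",
            cis,
        ]
        target.write("\t".join(row) + "\n")


def pattern_to_dot(pattern: TPattern) -> str:
    """DOT description of the binary construction tree with CI labels."""
    lines = ["digraph tpattern {", "  node [shape=box];"]
    counter = [0]

    def walk(node: Node) -> str:
        name = f"n{counter[0]}"
        counter[0] += 1
        if isinstance(node, EventType):
            lines.append(f'  {name} [label="{node.label}", shape=ellipse];')
        elif isinstance(node, BurstNode):
            lines.append(
                f'  {name} [label="burst({node.event_type.label}) '
                f'[0,{node.ci.d2}] p={node.ci.p_value:.3g}"];'
            )
        else:
            lines.append(
                f'  {name} [label="[{node.ci.d1},{node.ci.d2}] '
                f'p={node.ci.p_value:.3g}"];'
            )
            for child in (node.left, node.right):
                cname = walk(child)
                lines.append(f"  {name} -> {cname};")
        return name

    walk(pattern.structure)
    lines.append("}")
    return "\n".join(lines) + "\n"


def pattern_point_map(pattern: TPattern, data: TData) -> dict:
    """JSON-serializable point map: the involved series with their points
    and the level-by-level connections forming each occurrence."""
    missing = [
        lab for lab in pattern.terminal_labels if lab not in set(data.labels())
    ]
    if missing:
        raise KeyError(f"pattern event-types missing from data: {sorted(set(missing))}")
    involved = list(dict.fromkeys(pattern.terminal_labels))
    return {
        "pattern": pattern.label(),
        "terminals": list(pattern.terminal_labels),
        "series": {lab: data.get_series(lab).points for lab in involved},
        "occurrences": [list(f) for f in pattern.flat_occurrences()],
        "nodes": [
            {
                "d1": n.ci.d1,
                "d2": n.ci.d2,
                "p_value": n.ci.p_value,
                "n_hits": n.ci.n_hits,
            }
            for n in pattern.nodes()
        ],
        "levels": pattern.level,
    }


def export_pattern_diagram(
    pattern: TPattern, data: TData, target: str | Path
) -> tuple[Path, Path]:
    """Write the static diagram pair for one pattern.

    ``<target>.dot`` holds the binary tree with CI labels and
    ``<target>.json`` the point map connecting the involved series'
    points occurrence-by-occurrence. Returns the two paths.
    """
    base = Path(target)
    dot_path = base.with_suffix(".dot")
    json_path = base.with_suffix(".json")
    dot_path.write_text(pattern_to_dot(pattern))
    json_path.write_text(json.dumps(pattern_point_map(pattern, data), indent=2))
    return dot_path, json_path
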
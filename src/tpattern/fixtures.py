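"""Synthetic T-data and sequence generators with planted ground truth.

Real codings of behavior streams are rarely shareable, so tests and
examples run on synthetic data: independent uniform background point
series into which known multi-level patterns (fixed or jittered gaps),
bursts, or words are planted at known positions. The planted ground truth
is returned alongside the data so recovery can be scored mechanically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tdata import EventSeries, EventType, TData, TDataError

__all__ = [
    "PatternTemplate",
    "generate_noise_tdata",
    "plant_pattern",
    "generate_text_with_plants",
    "find_recovered_pattern",
]


@dataclass(frozen=True)
class PatternTemplate:
    """Blueprint for a planted pattern.

    ``gaps[i]`` separates terminal i from terminal i+1: either a fixed
    integer gap or an inclusive ``(g1, g2)`` range from which each
    instance draws uniformly (jitter). ``k`` is the occurrence count.
    """

    labels: tuple[str, ...]
    gaps: tuple[int | tuple[int, int], ...]
    k: int

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("template needs at least one terminal")
        if len(self.gaps) != len(self.labels) - 1:
            raise ValueError(
                f"{len(self.labels)} terminals need {len(self.labels) - 1} gaps"
            )
        for g in self.gaps:
            lo, hi = (g, g) if isinstance(g, int) else g
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid gap specification {g!r}")
        if self.k < 1:
            raise ValueError("occurrence count k must be >= 1")

    @property
    def max_span(self) -> int:
        return sum(g if isinstance(g, int) else g[1] for g in self.gaps)


def generate_noise_tdata(
    n_series: int, points_per_series: int, T: int, seed: int
) -> TData:
    """Independent uniform-without-replacement background series.

    Series are labeled ``noise_1 .. noise_n``; deterministic per seed.
    """
    if points_per_series > T:
        raise TDataError(
            f"cannot place {points_per_series} distinct points in [1, {T}]"
        )
    if n_series < 1 or points_per_series < 1:
        raise TDataError("need at least one series and one point per series")
    rng = np.random.default_rng(seed)
    series = []
    for i in range(1, n_series + 1):
        pts = rng.choice(T, size=points_per_series, replace=False) + 1
        series.append(EventSeries(EventType(f"noise_{i}"), sorted(int(t) for t in pts)))
    return TData(T=T, series=series)


def plant_pattern(
    data: TData,
    template: PatternTemplate,
    seed: int,
    noise_points: int = 0,
    avoid_spans: Sequence[tuple[int, int]] = (),
    _max_tries: int = 20_000,
) -> tuple[TData, list[tuple[int, ...]]]:
    """Plant ``k`` non-overlapping instances of a template into T-data.

    Instances are placed at random starts; fixed gaps are realized
    exactly, jittered gaps drawn uniformly within their range. Instances
    never overlap each other (nor any span in ``avoid_spans``), and
    planted times never collide with existing points of the same series.
    ``noise_points`` additionally scatters that many uniform background
    points into each of the template's own series, to test robustness.

    Returns the augmented TData and the ground-truth occurrence list
    (tuples of terminal times, sorted by start).
    """
    rng = np.random.default_rng(seed)
    taken: dict[str, set[int]] = {
        s.label: set(s.points) for s in data.series
    }
    for lab in template.labels:
        taken.setdefault(lab, set())
    spans: list[tuple[int, int]] = [tuple(sp) for sp in avoid_spans]
    occurrences: list[tuple[int, ...]] = []
    max_start = data.T - template.max_span
    if max_start < 1:
        raise TDataError("template span exceeds observation period")
    tries = 0
    while len(occurrences) < template.k:
        tries += 1
        if tries > _max_tries:
            raise TDataError(
                f"could not place {template.k} non-overlapping instances "
                f"(placed {len(occurrences)})"
            )
        start = int(rng.integers(1, max_start + 1))
        times = [start]
        for g in template.gaps:
            gap = g if isinstance(g, int) else int(rng.integers(g[0], g[1] + 1))
            times.append(times[-1] + gap)
        span = (times[0], times[-1])
        if any(not (span[1] < s or e < span[0]) for s, e in spans):
            continue
        if data.sample_index(span[0]) != data.sample_index(span[1]):
            continue
        if any(t in taken[lab] for lab, t in zip(template.labels, times)):
            continue
        # distinct terminals of the same label within one instance must
        # not collide either (zero gaps between equal labels)
        per_label: dict[str, set[int]] = {}
        ok = True
        for lab, t in zip(template.labels, times):
            if t in per_label.setdefault(lab, set()):
                ok = False
                break
            per_label[lab].add(t)
        if not ok:
            continue
        for lab, t in zip(template.labels, times):
            taken[lab].add(t)
        spans.append(span)
        occurrences.append(tuple(times))
    for lab in dict.fromkeys(template.labels):
        placed = 0
        while placed < noise_points:
            tries += 1
            if tries > _max_tries:
                raise TDataError("could not place background noise points")
            t = int(rng.integers(1, data.T + 1))
            if t not in taken[lab]:
                taken[lab].add(t)
                placed += 1

    etypes = {s.label: s.event_type for s in data.series}
    series = [
        EventSeries(etypes.get(lab, EventType.from_label(lab)), sorted(pts))
        for lab, pts in sorted(taken.items())
        if pts
    ]
    out = TData(T=data.T, series=series, sample_boundaries=list(data.sample_boundaries))
    occurrences.sort(key=lambda o: o[0])
    return out, occurrences


def generate_text_with_plants(
    length: int,
    alphabet: str,
    word: str,
    k: int,
    background_excludes_word_letters: bool,
    seed: int,
) -> tuple[str, list[int]]:
    """Uniform random text with a word planted at k non-overlapping spots.

    When ``background_excludes_word_letters`` the background is drawn from
    the alphabet minus the word's letters, isolating the recurrence signal
    (the planted copies are then the only occurrences of those letters).
    Returns the text and the 0-based insertion positions, sorted.
    """
    word = word.lower()
    if k * len(word) > length:
        raise TDataError("word copies do not fit in the requested length")
    pool = alphabet.lower()
    if background_excludes_word_letters:
        pool = "".join(c for c in pool if c not in set(word))
        if not pool:
            raise TDataError("alphabet minus word letters is empty")
    rng = np.random.default_rng(seed)
    chars = [pool[i] for i in rng.integers(0, len(pool), size=length)]
    positions: list[int] = []
    tries = 0
    while len(positions) < k:
        tries += 1
        if tries > 20_000:
            raise TDataError("could not place non-overlapping word copies")
        pos = int(rng.integers(0, length - len(word) + 1))
        if all(abs(pos - q) >= len(word) for q in positions):
            positions.append(pos)
    for pos in positions:
        chars[pos : pos + len(word)] = word
    return "".join(chars), sorted(positions)


def find_recovered_pattern(patterns, labels, ground_truth):
    """Score recovery of a planted pattern against detection output.

    A planted pattern counts as recovered when some detected pattern —
    itself, or a more complete pattern the completeness competition kept
    instead — contains, for every planted occurrence, all the planted
    ``(label, time)`` terminal points within a single occurrence.

    Returns the recovering pattern, or ``None``.
    """
    labels = tuple(labels)
    for p in patterns:
        seq = p.terminal_labels
        flats = p.flat_occurrences()
        ok = True
        for planted in ground_truth:
            needed = list(zip(labels, planted))
            if not any(
                _ordered_points_within(needed, list(zip(seq, flat)))
                for flat in flats
            ):
                ok = False
                break
        if ok:
            return p
    return None


def _ordered_points_within(needed, points) -> bool:
    """Are the (label, time) pairs an ordered sub-sequence of points?"""
    it = iter(points)
    return all(any(n == q for q in it) for n in needed)
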
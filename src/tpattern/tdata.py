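"""Data model and I/O for T-data.

T-data are one or more *samples* of discrete occurrence-point series of
categorical event-types within a continuous observation period ``[1, T]``.
Time is discrete (positive integers, coded time units); sub-second data are
expected to be pre-scaled by the caller.

The on-disk dialect is the two-column tab-separated text file
``<time>\\t<event-type label>``, one row per occurrence.
"""

from __future__ import annotations

import io
import json
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence, TextIO

__all__ = [
    "EventType",
    "EventSeries",
    "TData",
    "read_tdata",
    "write_tdata",
    "concatenate_samples",
    "sequence_to_tdata",
    "fasta_to_tdata",
    "TDataError",
]

#: Default alphabets for sequence conversion.
TEXT_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
DNA_ALPHABET = "acgt"
PROTEIN_ALPHABET = "acdefghiklmnpqrstvwy"


class TDataError(ValueError):
    """Raised for malformed or inconsistent T-data."""


@dataclass(frozen=True)
class EventType:
    """A coded category whose occurrences form one point series.

    Labels following the ``actor,phase,behavior`` convention (e.g.
    ``x,b,look`` — actor *x* begins looking) are decomposed so that
    multi-actor pattern statistics can be computed; any other label is
    kept opaque with no actor attached.
    """

    label: str
    actor: str | None = None
    phase: str | None = None
    behavior: str | None = None

    @classmethod
    def from_label(cls, label: str) -> "EventType":
        if not label:
            raise TDataError("event-type label must be non-empty")
        parts = label.split(",")
        if len(parts) == 3 and all(parts) and parts[1] in ("b", "e"):
            return cls(label, actor=parts[0], phase=parts[1], behavior=parts[2])
        return cls(label)


@dataclass
class EventSeries:
    """One event-type with its sorted occurrence points."""

    event_type: EventType
    points: list[int]

    def __post_init__(self) -> None:
        pts = list(self.points)
        if any(p != int(p) or p < 1 for p in pts):
            raise TDataError(
                f"series {self.event_type.label!r}: points must be positive integers"
            )
        for a, b in zip(pts, pts[1:]):
            if b <= a:
                raise TDataError(
                    f"series {self.event_type.label!r}: points must be strictly "
                    f"increasing (duplicate or unsorted at t={b})"
                )
        self.points = pts

    @property
    def label(self) -> str:
        return self.event_type.label

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TData:
    """Observation period ``[1, T]`` plus named occurrence-point series.

    ``sample_boundaries`` lists the end time of each sample in a
    (possibly concatenated) multi-sample file; a single-sample TData has
    ``sample_boundaries == [T]``.
    """

    T: int
    series: list[EventSeries] = field(default_factory=list)
    sample_boundaries: list[int] | None = None

    def __post_init__(self) -> None:
        if self.T < 1:
            raise TDataError(f"observation period T must be >= 1, got {self.T}")
        if self.sample_boundaries is None:
            self.sample_boundaries = [self.T]
        bounds = self.sample_boundaries
        if sorted(bounds) != bounds or len(set(bounds)) != len(bounds):
            raise TDataError("sample boundaries must be strictly increasing")
        if bounds[-1] != self.T:
            raise TDataError("last sample boundary must equal T")
        if bounds[0] < 1:
            raise TDataError("sample boundaries must be >= 1")
        labels = [s.label for s in self.series]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TDataError(f"duplicate series labels: {dupes}")
        for s in self.series:
            if s.points and (s.points[0] < 1 or s.points[-1] > self.T):
                raise TDataError(
                    f"series {s.label!r} has points outside [1, {self.T}]"
                )

    # -- sample geometry -------------------------------------------------

    def sample_starts(self) -> list[int]:
        """First time unit of each sample."""
        return [1] + [b + 1 for b in self.sample_boundaries[:-1]]

    def sample_index(self, t: int) -> int:
        """Index of the sample containing time ``t``."""
        return bisect_left(self.sample_boundaries, t)

    def sample_end(self, t: int) -> int:
        """End time of the sample containing ``t``."""
        return self.sample_boundaries[self.sample_index(t)]

    def sample_span(self, k: int) -> tuple[int, int]:
        """(start, end) times of sample ``k``."""
        start = 1 if k == 0 else self.sample_boundaries[k - 1] + 1
        return start, self.sample_boundaries[k]

    @property
    def n_samples(self) -> int:
        return len(self.sample_boundaries)

    # -- access ----------------------------------------------------------

    def get_series(self, label: str) -> EventSeries:
        for s in self.series:
            if s.label == label:
                return s
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [s.label for s in self.series]

    def total_points(self) -> int:
        return sum(len(s) for s in self.series)

    def to_json(self) -> str:
        """JSON dump for debugging and manifests."""
        return json.dumps(
            {
                "T": self.T,
                "sample_boundaries": self.sample_boundaries,
                "series": {s.label: s.points for s in self.series},
            },
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# I/O


def read_tdata(source: TextIO | str, T: int | None = None) -> TData:
    """Parse the two-column ``<time>\\t<label>`` dialect into a TData.

    If ``T`` is not given it defaults to the maximum observed time.
    Duplicate (time, label) rows are rejected rather than deduplicated:
    they usually indicate coding errors and should be surfaced.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    rows: list[tuple[int, str]] = []
    seen: dict[tuple[int, str], int] = {}
    dupes: list[str] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[1]:
            raise TDataError(
                f"line {lineno}: expected '<time>\\t<event-type>', got {line!r}"
            )
        time_str, label = parts
        try:
            t = int(time_str)
        except ValueError:
            raise TDataError(f"line {lineno}: non-integer time {time_str!r}") from None
        if t < 1:
            raise TDataError(f"line {lineno}: non-positive time {t}")
        key = (t, label)
        if key in seen:
            dupes.append(f"({t}, {label!r}) at lines {seen[key]} and {lineno}")
        else:
            seen[key] = lineno
        rows.append((t, label))
    if dupes:
        raise TDataError("duplicate (time, event-type) rows: " + "; ".join(dupes))
    if not rows:
        raise TDataError("no events in input")
    max_t = max(t for t, _ in rows)
    if T is None:
        T = max_t
    elif max_t > T:
        raise TDataError(f"event at t={max_t} exceeds observation period T={T}")
    by_label: dict[str, list[int]] = {}
    for t, label in rows:
        by_label.setdefault(label, []).append(t)
    series = [
        EventSeries(EventType.from_label(label), sorted(pts))
        for label, pts in sorted(by_label.items())
    ]
    return TData(T=T, series=series)


def write_tdata(data: TData, target: TextIO) -> None:
    """Write a TData in the two-column dialect, rows sorted by (time, label).

    ``read_tdata(write_tdata(x))`` reproduces ``x`` (up to the implicit T
    when no trailing event marks the period end).
    """
    rows: list[tuple[int, str]] = []
    for s in data.series:
        if "\t" in s.label or "\n" in s.label:
            raise TDataError(
                f"label {s.label!r} contains tab/newline; not representable"
            )
        rows.extend((t, s.label) for t in s.points)
    rows.sort()
    for t, label in rows:
        target.write(f"{t}\t{label}\n")


def concatenate_samples(samples: Sequence[TData]) -> TData:
    """Concatenate single- or multi-sample TData into one multi-sample TData.

    Sample k is shifted by the sum of the preceding observation periods;
    series with equal labels are merged. Baseline probabilities downstream
    use the concatenated total T and counts.
    """
    if not samples:
        raise TDataError("cannot concatenate an empty list of samples")
    offset = 0
    boundaries: list[int] = []
    merged: dict[str, list[int]] = {}
    etypes: dict[str, EventType] = {}
    for sample in samples:
        for b in sample.sample_boundaries:
            boundaries.append(b + offset)
        for s in sample.series:
            etypes.setdefault(s.label, s.event_type)
            merged.setdefault(s.label, []).extend(t + offset for t in s.points)
        offset += sample.T
    series = [
        EventSeries(etypes[label], sorted(pts)) for label, pts in sorted(merged.items())
    ]
    return TData(T=offset, series=series, sample_boundaries=boundaries)


# ---------------------------------------------------------------------------
# Sequence conversion ([1,1]-restricted analysis of strings)


def sequence_to_tdata(sequence: str, alphabet: str | None = None) -> TData:
    """Convert a symbol string into T-data for [1,1]-restricted detection.

    Position ``i`` (1-based) of symbol ``s`` becomes point ``i`` in series
    ``s``, so T equals the sequence length and every position contributes
    exactly one point. The string is lowercased; characters outside
    ``alphabet`` (default: a-z) are dropped before positions are assigned,
    mirroring blanks-removed text analysis.
    """
    if alphabet is None:
        alphabet = TEXT_ALPHABET
    allowed = set(alphabet.lower())
    symbols = [c for c in sequence.lower() if c in allowed]
    if not symbols:
        raise TDataError("sequence empty after normalization")
    by_symbol: dict[str, list[int]] = {}
    for i, c in enumerate(symbols, start=1):
        by_symbol.setdefault(c, []).append(i)
    series = [
        EventSeries(EventType(sym), pts) for sym, pts in sorted(by_symbol.items())
    ]
    return TData(T=len(symbols), series=series)


def fasta_to_tdata(source: TextIO | str, alphabet: str | None = None):
    """Yield ``(record_id, TData)`` per FASTA record.

    Residue alphabets default to DNA if the record uses only ACGTN,
    otherwise the 20 amino-acid codes.
    """
    from Bio import SeqIO

    if isinstance(source, str):
        source = io.StringIO(source)
    for record in SeqIO.parse(source, "fasta"):
        seq = str(record.seq).lower()
        if alphabet is None:
            alpha = DNA_ALPHABET if set(seq) <= set("acgtn") else PROTEIN_ALPHABET
        else:
            alpha = alphabet
        yield record.id, sequence_to_tdata(seq, alphabet=alpha)
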
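"""Critical-interval statistics.

The glue relation of T-pattern analysis: two point series A and B are
related by a *critical interval* ``[d1, d2]`` when, significantly more
often than expected under independent random placement, an occurrence of
A at time ``a`` is followed by an occurrence of B within ``[a+d1, a+d2]``.

Null model: B's points are treated as independent per-unit presence with
rate ``N_B / T``, so a window of ``w`` discrete units contains at least one
B point with probability ``1 - (1 - N_B/T)**w``. The number of A points
whose window is hit is then binomial (Poisson-binomial when windows are
truncated at sample boundaries and so differ in width), and the reported
p-value is the exact upper tail at the observed hit count.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.stats import binom

__all__ = [
    "CriticalInterval",
    "DetectionParams",
    "null_prob_window",
    "ci_pvalue",
    "detect_critical_interval",
]

Mode = Literal["general", "burst", "fixed_11"]


@dataclass(frozen=True)
class CriticalInterval:
    """A significant window ``[d1, d2]`` with its test outcome."""

    d1: int
    d2: int
    p_value: float
    n_hits: int

    def __post_init__(self) -> None:
        if not (0 <= self.d1 <= self.d2):
            raise ValueError(f"need 0 <= d1 <= d2, got [{self.d1}, {self.d2}]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def width(self) -> int:
        return self.d2 - self.d1 + 1


@dataclass(frozen=True)
class DetectionParams:
    """Search parameters for T-pattern detection.

    ``alpha`` defaults to 0.005, the conventional default significance
    level for this analysis; ``n_min`` is the minimum number of pattern
    occurrences (hard floor 2 — one co-occurrence is not recurrence).
    ``d_max`` caps the critical-interval end (default: T-1, i.e. no cap
    beyond the observation period). ``max_levels`` bounds construction
    passes and ``max_length`` the terminal count of built patterns.
    """

    alpha: float = 0.005
    n_min: int = 3
    d_max: int | None = None
    max_levels: int = 10
    max_length: int = 10
    mode: Mode = "general"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_min < 2:
            raise ValueError(f"n_min must be >= 2, got {self.n_min}")
        if self.d_max is not None and self.d_max < 0:
            raise ValueError(f"d_max must be >= 0, got {self.d_max}")
        if self.mode not in ("general", "burst", "fixed_11"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def effective_d_max(self, T: int) -> int:
        return T - 1 if self.d_max is None else min(self.d_max, T - 1)

    def with_mode(self, mode: Mode) -> "DetectionParams":
        return replace(self, mode=mode)


def null_prob_window(n_b: int, T: int, w: int) -> float:
    """P(window of ``w`` units contains >= 1 B point) under the null.

    Monotone non-decreasing in both ``n_b`` and ``w``.
    """
    if n_b < 0 or T < 1 or w < 0:
        raise ValueError(f"invalid arguments n_b={n_b}, T={T}, w={w}")
    if n_b > T:
        raise ValueError(f"n_b={n_b} exceeds T={T}")
    if w == 0 or n_b == 0:
        return 0.0
    if n_b == T:
        return 1.0
    return float(-np.expm1(w * np.log1p(-n_b / T)))


def _poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """Exact P(X >= k) for a sum of independent Bernoulli(p_i)."""
    if k <= 0:
        return 1.0
    n = len(probs)
    if k > n:
        return 0.0
    dp = np.zeros(n + 1)
    dp[0] = 1.0
    for i, p in enumerate(probs):
        dp[1 : i + 2] = dp[1 : i + 2] * (1.0 - p) + dp[: i + 1] * p
        dp[0] *= 1.0 - p
    return float(min(1.0, dp[k:].sum()))


def _truncated_widths(
    a_points: Sequence[int], d1: int, d2: int, ends: Sequence[int]
) -> list[int]:
    """Window widths per left point, truncated at each point's sample end."""
    return [
        max(0, min(a + d2, e) - (a + d1) + 1) for a, e in zip(a_points, ends)
    ]


def _sample_ends(points: Sequence[int], boundaries: Sequence[int]) -> list[int]:
    return [boundaries[bisect_left(boundaries, t)] for t in points]


def _count_hits(
    a_points: Sequence[int],
    b_points: Sequence[int],
    d1: int,
    d2: int,
    ends: Sequence[int],
) -> int:
    hits = 0
    for a, e in zip(a_points, ends):
        lo, hi = a + d1, min(a + d2, e)
        if hi >= lo:
            i = bisect_left(b_points, lo)
            if i < len(b_points) and b_points[i] <= hi:
                hits += 1
    return hits


def ci_pvalue(
    a_points: Sequence[int],
    b_points: Sequence[int],
    T: int,
    d1: int,
    d2: int,
    boundaries: Sequence[int] | None = None,
) -> tuple[float, int]:
    """Exact upper-tail p-value for the window test of ``[d1, d2]``.

    ``n_hits`` counts A points with at least one B point in
    ``[a+d1, a+d2]`` within the same sample; the p-value is the exact
    tail P(X >= n_hits) with per-trial probabilities from
    :func:`null_prob_window` at each (boundary-truncated) window width.

    Returns ``(1.0, 0)`` when either series is empty.
    """
    if not (0 <= d1 <= d2):
        raise ValueError(f"need 0 <= d1 <= d2, got [{d1}, {d2}]")
    if boundaries is None:
        boundaries = [T]
    a_points = sorted(a_points)
    b_points = sorted(b_points)
    if not a_points or not b_points:
        return 1.0, 0
    ends = _sample_ends(a_points, boundaries)
    n_hits = _count_hits(a_points, b_points, d1, d2, ends)
    widths = _truncated_widths(a_points, d1, d2, ends)
    n_b = len(b_points)
    probs = [null_prob_window(n_b, T, w) for w in widths]
    if len(set(widths)) == 1:
        p = float(binom.sf(n_hits - 1, len(a_points), probs[0]))
    else:
        p = _poisson_binomial_tail(probs, n_hits)
    return min(1.0, max(0.0, p)), n_hits


# ---------------------------------------------------------------------------
# Critical-interval search


def _nearest_follower_distances(
    a_points: Sequence[int],
    b_points: Sequence[int],
    d_max: int,
    boundaries: Sequence[int],
) -> list[int]:
    """Distinct forward distances from each A point to its nearest
    following same-sample B point (capped at ``d_max``)."""
    out: set[int] = set()
    for a in a_points:
        end = boundaries[bisect_left(boundaries, a)]
        i = bisect_left(b_points, a)
        if i < len(b_points) and b_points[i] - a <= min(d_max, end - a):
            out.add(b_points[i] - a)
    return sorted(out)


def _sidak_adjust(p: float, n_tests: int) -> float:
    """Family-wise adjustment of the selected minimum p-value."""
    if n_tests <= 1:
        return p
    return float(-np.expm1(n_tests * np.log1p(-min(p, 1.0))))


def _select_best(
    cands: list[tuple[int, int, int]],
    pvals: np.ndarray,
    alpha: float,
    n_tests: int,
) -> CriticalInterval | None:
    best: tuple[float, int, int, int, int] | None = None
    for (d1, d2, n_hits), p in zip(cands, pvals):
        if _sidak_adjust(float(p), n_tests) > alpha:
            continue
        key = (p, d2 - d1, d1)
        if best is None or key < best[:3]:
            best = (float(p), d2 - d1, d1, d2, n_hits)
    if best is None:
        return None
    p, _, d1, d2, n_hits = best
    return CriticalInterval(d1=d1, d2=d2, p_value=p, n_hits=n_hits)


def detect_critical_interval(
    a_points: Sequence[int],
    b_points: Sequence[int],
    T: int,
    params: DetectionParams,
    boundaries: Sequence[int] | None = None,
) -> CriticalInterval | None:
    """Search for the most significant critical interval relating A to B.

    Candidate intervals ``[d1, d2]`` take both endpoints from the set of
    distances from each A point to its *nearest following* B point
    (same sample, capped at ``d_max``) — the first-response reading of
    "B follows A within a characteristic window". Hit counting and the
    exact tail test then use the full window (any B point qualifies).
    The winner minimises the exact p-value, tie-broken by smaller width
    then smaller ``d1``; because the winner is selected among several
    candidates, significance is gated on a Šidák adjustment of its
    p-value at the effective number of tests (the count of distinct
    candidate endpoints). Returns ``None`` when no candidate passes the
    gate with at least ``n_min`` hits — a normal outcome.

    In mode ``fixed_11`` only ``[1, 1]`` is tested (no adjustment); in
    mode ``burst`` (a series against itself) only ``[0, d2]`` candidates
    over successive-point gaps are tested, adjusted likewise.
    """
    if boundaries is None:
        boundaries = [T]
    a_points = sorted(a_points)
    b_points = sorted(b_points)
    if not a_points or not b_points:
        return None
    d_max = params.effective_d_max(T)

    if params.mode == "fixed_11":
        if d_max < 1:
            return None
        p, n_hits = ci_pvalue(a_points, b_points, T, 1, 1, boundaries)
        if p <= params.alpha and n_hits >= params.n_min:
            return CriticalInterval(1, 1, p, n_hits)
        return None

    if params.mode == "burst":
        return _detect_burst_interval(a_points, T, params, boundaries)

    if len(b_points) >= T:
        return None  # saturated null: a window can never be surprising
    dists = _nearest_follower_distances(a_points, b_points, d_max, boundaries)
    if not dists:
        return None
    ends = _sample_ends(a_points, boundaries)
    # Windows wider than the mean B spacing are expected to contain a B
    # point under the null — no predictive surprise — and violate the
    # near-independence the binomial tail assumes (overlapping windows).
    w_max = max(1, T // len(b_points))
    cands: list[tuple[int, int, int]] = []
    for i, d1 in enumerate(dists):
        for d2 in dists[i:]:
            if d2 - d1 + 1 > w_max:
                break
            n_hits = _count_hits(a_points, b_points, d1, d2, ends)
            if n_hits >= params.n_min:
                cands.append((d1, d2, n_hits))
    if not cands:
        return None
    pvals = _candidate_pvalues(cands, a_points, len(b_points), T, boundaries)
    return _select_best(cands, pvals, params.alpha, n_tests=len(dists))


def _candidate_pvalues(
    cands: list[tuple[int, int, int]],
    a_points: Sequence[int],
    n_b: int,
    T: int,
    boundaries: Sequence[int],
) -> np.ndarray:
    """Exact tail p-values for all candidates, vectorised where windows
    are untruncated (the common case)."""
    ends = _sample_ends(a_points, boundaries)
    a_arr = np.asarray(a_points)
    e_arr = np.asarray(ends)
    d1_arr = np.array([c[0] for c in cands])
    d2_arr = np.array([c[1] for c in cands])
    hits_arr = np.array([c[2] for c in cands])
    n_a = len(a_points)
    # candidates whose every window stays inside its sample: plain binomial
    max_slack = int((e_arr - a_arr).min())
    uniform = d2_arr <= max_slack
    pvals = np.empty(len(cands))
    if uniform.any():
        w = d2_arr[uniform] - d1_arr[uniform] + 1
        p0 = -np.expm1(w * np.log1p(-n_b / T))
        pvals[uniform] = binom.sf(hits_arr[uniform] - 1, n_a, p0)
    trunc = np.flatnonzero(~uniform)
    if trunc.size:
        # per-trial window widths differ once truncated: exact
        # Poisson-binomial tail, dynamic programme vectorised over candidates
        W = np.clip(
            np.minimum(a_arr[None, :] + d2_arr[trunc, None], e_arr[None, :])
            - (a_arr[None, :] + d1_arr[trunc, None])
            + 1,
            0,
            None,
        )
        P = -np.expm1(W * np.log1p(-n_b / T))
        C = trunc.size
        dp = np.zeros((C, n_a + 1))
        dp[:, 0] = 1.0
        for j in range(n_a):
            pj = P[:, j : j + 1]
            dp[:, 1:] = dp[:, 1:] * (1.0 - pj) + dp[:, :-1] * pj
            dp[:, 0] *= 1.0 - pj[:, 0]
        suffix = dp[:, ::-1].cumsum(axis=1)[:, ::-1]
        pvals[trunc] = suffix[np.arange(C), hits_arr[trunc]]
    return np.clip(pvals, 0.0, 1.0)


def _detect_burst_interval(
    points: Sequence[int],
    T: int,
    params: DetectionParams,
    boundaries: Sequence[int],
) -> CriticalInterval | None:
    """Fast-interval ``[0, d2]`` search of a series against itself.

    Trials are the successive same-sample gaps; a gap <= d2 is a hit.
    The self-distance 0 is excluded (a point cannot be its own follower),
    so the effective window after each point spans ``d2`` units and the
    per-trial null probability is ``1 - (1 - n/T)**d2``.
    """
    if len(points) < 2:
        return None
    ends = _sample_ends(points, boundaries)
    gaps = [
        b - a
        for a, b, e in zip(points, points[1:], ends)
        if b <= e  # successor within the same sample
    ]
    n = len(points)
    d_max = min(params.effective_d_max(T), max(1, T // n))
    n_trials = len(gaps)  # every successive same-sample gap is a trial
    distinct = sorted({g for g in gaps if g <= d_max})
    if not distinct:
        return None
    # the recurrence floor n_min applies to pattern occurrences, not to
    # gap hits: a single sufficiently tight run is already a burst
    best: tuple[float, int, int] | None = None
    for d2 in distinct:
        n_hits = sum(1 for g in gaps if g <= d2)
        p0 = null_prob_window(n, T, d2)
        p = float(binom.sf(n_hits - 1, n_trials, p0))
        if _sidak_adjust(p, len(distinct)) <= params.alpha and (
            best is None or (p, d2) < best[:2]
        ):
            best = (p, d2, n_hits)
    if best is None:
        return None
    p, d2, n_hits = best
    return CriticalInterval(0, d2, p, n_hits)
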
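"""Surrogate-data Monte Carlo validation.

Because T-pattern detection performs many significance tests, some
patterns are found even in random data. Two randomizations quantify this:

* **T-shuffling** replaces each series with uniformly random (distinct)
  times within its sample, destroying all temporal structure while
  preserving per-series, per-sample counts.
* **T-rotation** circularly shifts each series by a random offset within
  its sample, preserving each series' internal (circular) inter-point
  interval structure while destroying cross-series alignment.

Detection is re-run on each surrogate with byte-identical parameters, and
the number of *different* patterns of each length is compared with the
counts from the original data (mean and standard deviation across
surrogates; the conventional display adds one standard deviation to the
surrogate mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ci_stats import DetectionParams
from .engine import TPattern, detect_tpatterns
from .tdata import EventSeries, TData, TDataError

__all__ = [
    "MonteCarloResult",
    "shuffle_tdata",
    "rotate_tdata",
    "monte_carlo_validate",
    "pattern_length_counts",
]


@dataclass
class MonteCarloResult:
    """Observed per-length pattern counts vs. surrogate baselines."""

    method: str
    n_randomizations: int
    observed: dict[int, int]
    surrogate_mean: dict[int, float]
    surrogate_sd: dict[int, float]

    def lengths(self) -> list[int]:
        keys = set(self.observed) | set(self.surrogate_mean)
        return sorted(keys)

    def row(self, length: int) -> tuple[int, int, float, float]:
        return (
            length,
            self.observed.get(length, 0),
            self.surrogate_mean.get(length, 0.0),
            self.surrogate_sd.get(length, 0.0),
        )

    def exceeds_mean_plus_sd(self, length: int, k: float = 1.0) -> bool:
        """Is the observed count above surrogate mean + k*SD at ``length``?"""
        _, obs, mean, sd = self.row(length)
        return obs > mean + k * sd


def pattern_length_counts(patterns: list[TPattern]) -> dict[int, int]:
    """Number of different patterns of each length."""
    counts: dict[int, int] = {}
    for p in patterns:
        counts[p.m] = counts.get(p.m, 0) + 1
    return counts


def shuffle_tdata(data: TData, seed: int) -> TData:
    """T-shuffling surrogate: uniform redraw of every series per sample.

    Points are drawn without replacement (series points are distinct by
    invariant) from the sample's time range; per-series, per-sample
    counts, T and labels are preserved.
    """
    rng = np.random.default_rng(seed)
    new_series = []
    for s in data.series:
        pts: list[int] = []
        for k in range(data.n_samples):
            start, end = data.sample_span(k)
            in_sample = [t for t in s.points if start <= t <= end]
            L = end - start + 1
            if len(in_sample) > L:
                raise TDataError(
                    f"series {s.label!r}: {len(in_sample)} points exceed "
                    f"sample length {L}"
                )
            if in_sample:
                draw = rng.choice(L, size=len(in_sample), replace=False)
                pts.extend(int(start + d) for d in draw)
        new_series.append(EventSeries(s.event_type, sorted(pts)))
    return TData(T=data.T, series=new_series, sample_boundaries=list(data.sample_boundaries))


def rotate_tdata(data: TData, seed: int) -> TData:
    """T-rotation surrogate: circular shift of every series per sample.

    Each series is shifted by its own random ``dt`` drawn uniformly from
    ``{1, .., L-1}`` (``L`` = sample length), wrapping around the sample:
    ``t -> ((t - start + dt) mod L) + start``. The circular gap multiset
    of each series is preserved; samples of length 1 are left unchanged.
    """
    rng = np.random.default_rng(seed)
    new_series = []
    for s in data.series:
        pts: list[int] = []
        for k in range(data.n_samples):
            start, end = data.sample_span(k)
            in_sample = [t for t in s.points if start <= t <= end]
            L = end - start + 1
            if not in_sample:
                continue
            if L == 1:
                pts.extend(in_sample)
                continue
            dt = int(rng.integers(1, L))
            pts.extend(((t - start + dt) % L) + start for t in in_sample)
        new_series.append(EventSeries(s.event_type, sorted(pts)))
    return TData(T=data.T, series=new_series, sample_boundaries=list(data.sample_boundaries))


_SURROGATES = {"shuffle": shuffle_tdata, "rotation": rotate_tdata}


def monte_carlo_validate(
    data: TData,
    params: DetectionParams,
    method: str = "shuffle",
    n_randomizations: int = 50,
    seed: int = 0,
) -> MonteCarloResult:
    """Compare detected per-length pattern counts against surrogates.

    Runs :func:`~tpattern.engine.detect_tpatterns` once on ``data`` and
    once per surrogate (identical parameters), tallying the number of
    different patterns of each length, and reports the surrogate mean and
    population standard deviation per length.
    """
    if method not in _SURROGATES:
        raise ValueError(f"method must be one of {sorted(_SURROGATES)}, got {method!r}")
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    randomize = _SURROGATES[method]
    observed = pattern_length_counts(detect_tpatterns(data, params))
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_randomizations)
    tallies: list[dict[int, int]] = []
    for s in sub_seeds:
        surrogate = randomize(data, int(s))
        tallies.append(pattern_length_counts(detect_tpatterns(surrogate, params)))
    lengths = sorted(set(observed) | {m for t in tallies for m in t})
    mean: dict[int, float] = {}
    sd: dict[int, float] = {}
    for m in lengths:
        vals = np.array([t.get(m, 0) for t in tallies], dtype=float)
        mean[m] = float(vals.mean())
        sd[m] = float(vals.std())  # population SD across surrogates
    return MonteCarloResult(
        method=method,
        n_randomizations=n_randomizations,
        observed=observed,
        surrogate_mean=mean,
        surrogate_sd=sd,
    )
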
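# Methods

## Data model

T-data are a discrete observation period `[1, T]` (positive integer time
units; sub-second data are pre-scaled by the user) plus one strictly
increasing occurrence-point series per event-type. A multi-sample file
concatenates independent recordings; `sample_boundaries` records each
sample's end time. All baseline probabilities use the concatenated
file's total `T` and total per-series counts (per-sample baselines are
not computed), but windows, pairings and burst runs never cross a
sample boundary: samples are independent recordings, so a "distance"
spanning two of them would be an artifact. Duplicate (time, event-type)
rows are rejected rather than deduplicated — in coded observational
data they almost always indicate coding errors.

Sequences (text, DNA, protein) map to T-data by giving every symbol its
own series: position `i` of symbol `s` becomes point `i` of series `s`.
Input is lowercased and characters outside the declared alphabet are
dropped before positions are assigned (the blanks-removed convention
for text).

## The critical-interval test

For series A (N_A points) and B (N_B points), the null model treats B
as independent per-unit presence at rate `N_B/T`, so a window of `w`
units contains at least one B point with probability
`p0 = 1 - (1 - N_B/T)^w`. The test statistic is the number of A points
with at least one B point in `[a+d1, a+d2]` (same sample; windows are
truncated at the sample end, for both hit counting and `p0`). With
equal windows the p-value is the exact binomial upper tail; with
truncation-induced unequal widths it is the exact Poisson-binomial
tail, computed by dynamic programming. `ci_pvalue` is cross-checked in
the tests against full enumeration over hit configurations and against
Monte Carlo frequencies.

### Search and selection

Candidate intervals take both endpoints from the set of distances from
each A point to its *nearest following* B point — the first-response
(renewal) reading of "B follows A within a characteristic window",
which keeps the candidate family small and data-supported. Hits are
then counted over the full window (any B point qualifies). Three
guards shape the search:

* **Width cap.** Intervals wider than the mean B spacing `T // N_B` are
  skipped: under the null such a window is *expected* to contain a B
  point, so a "significant" wide interval carries no predictive
  surprise, and overlapping windows violate the near-independence the
  binomial tail assumes.
* **Selection adjustment.** The minimum-p candidate is significant only
  if its Šidák-adjusted p-value at the effective number of tests — the
  number of distinct candidate endpoints `D` — clears α. This is a
  deliberate middle ground: no adjustment makes nearly every pair of
  independent series "significant" (the minimum over a correlated
  family is far from a single test), while a full adjustment over all
  `D(D+1)/2` intervals (or over all possible window positions) would
  remove the sensitivity that makes two-occurrence detection possible
  at all — a pattern seen exactly twice with a one-unit window has a
  raw tail near 1e-4, the same order as the extremes of the noise
  distribution. The residual permissiveness is deliberate and is
  controlled globally by surrogate validation (below), which is how
  this family of methods handles its multiplicity in practice.
* **Deterministic tie-breaks.** Among significant candidates the winner
  minimizes the raw p-value, then interval width, then `d1`.

In mode `fixed_11` only `[1,1]` is tested (one test, no adjustment). In
burst mode a series is tested against itself over fast intervals
`[0, d2]`, `d2` drawn from the observed successive-point gaps; every
same-sample successive gap is a trial, the per-trial null probability
is `1 - (1 - n/T)^{d2}` (the self-distance 0 cannot occur), and the
same Šidák adjustment applies over the distinct gap candidates. The
recurrence floor `n_min` does not gate burst hits: a single
sufficiently tight run is already a burst.

## Pattern construction

Detection is bottom-up. The working set starts with all event series
(plus per-series bursts in burst mode). Each pass tests every ordered
pair of distinct working series — left end-points against right
start-points, total terminal count capped by `max_length` — and builds
a candidate pattern from each significant interval by greedy earliest
pairing: left occurrences in start order, each joined to the earliest
unused right occurrence whose start lies in the interval, in the same
sample, and sharing no underlying point with the left occurrence (a
component cannot double as part of its own context; without this rule
the search builds degenerate chains like `(A (A B))` out of single
points). Candidates with at least `n_min` paired occurrences survive to
the completeness competition; survivors join the working set, and the
loop stops at a fixpoint or after `max_levels` passes.

The **completeness competition** removes redundant detections: (1)
among patterns with identical terminal sequence and occurrence times
but different tree shapes, the one with the smallest maximal node
p-value survives; (2) a pattern P is dropped when a pattern Q exists
with equally many occurrences whose terminal sequence contains P's as
an ordered subsequence and whose occurrences contain P's occurrences
*point for point* — P is then a partial detection of Q. Containment is
by identical terminal points, not by time-span overlap: span overlap
would let unrelated chance patterns swallow genuine detections.

Every reported pattern can be re-verified from raw T-data
(`verify_pattern`): terminal conservation, per-node realized gaps
within their intervals, within-sample occurrences, no point reuse,
recurrence and significance floors. The tests also compare the whole
pipeline against an exhaustive plain-Python re-implementation on micro
instances.

## Surrogate validation

`monte_carlo_validate` re-runs detection with byte-identical parameters
on randomized copies of the data and reports, per pattern length, the
observed count of different patterns against the surrogate mean and
population SD (the conventional display adds one SD to the mean).
T-shuffling redraws each series uniformly without replacement within
its sample (counts preserved, all temporal structure destroyed);
T-rotation circularly shifts each series by its own `dt` uniform in
`{1..L-1}` per sample via `t -> ((t - start + dt) mod L) + start`,
preserving each series' circular gap multiset. The textbook rotation
formula `(t + dt) mod T` can yield 0; the shift into `[1, T]` is the
only departure. One `dt` is drawn per series (and per sample), not one
shared shift.

## Parameters

| parameter    | default | meaning                                               |
|--------------|---------|-------------------------------------------------------|
| `alpha`      | 0.005   | significance level of the critical-interval test      |
| `n_min`      | 3       | minimum pattern occurrences (hard floor 2)            |
| `d_max`      | T-1     | cap on interval end                                   |
| `max_levels` | 10      | construction passes                                   |
| `max_length` | 10      | terminal count cap (word search raises it to the target length) |
| `mode`       | general | `general`, `burst`, or `fixed_11`                     |

α = 0.005 is the conventional default for this analysis; it is a user
decision, not estimated from data.

## Synthetic data

Real coded interaction corpora are not redistributable, so all tests
and examples run on generated data: independent uniform background
series, planted multi-level patterns with fixed or jittered gaps
(ground-truth occurrences returned for mechanical recovery scoring),
planted dense runs, and random texts with planted words. The generator
reproduces the *structure* of coded behavior streams — categorical
point series, hierarchical recurrence with translation symmetry — but
not their texture: no autocorrelation or refractoriness within series,
no cross-series rate coupling, no natural-language letter dependencies.
Passing tests therefore demonstrate correctness of the machinery and
its calibration against its own null, not performance on real
recordings.

Recovery of a planted pattern is scored against the returned ground
truth: a pattern counts as recovered when some detected pattern —
itself, or the more complete pattern the competition kept instead —
contains all planted (label, time) points of every planted occurrence.

Test problem sizes are desk-scale by design: detection fixtures use
3-8 series of 10-20 points on T = 10^4; the word fixture uses the full
10,103-letter text; Monte Carlo calibration uses four series of twenty
points on T = 10^4 (the reference per-series density with fewer
series), 20 surrogates, 50 seeds.

## Numerical choices and degenerate inputs

Exact tails throughout (binomial via `scipy.stats.binom.sf`,
Poisson-binomial via an O(n²) DP); `log1p/expm1` for `p0`; a saturated
null (`N_B = T`) is never significant; empty series yield `(1.0, 0)`
from `ci_pvalue` and no interval from the search; series with fewer
than two points yield no bursts; a sample of length 1 is left unchanged
by rotation. Detection is fully deterministic: identical input and
parameters give identical output, and surrogate generators are
deterministic per seed.

## Known limitations

* **Binary trees only.** A pattern whose parts are individually
  non-significant cannot be assembled; in `[1,1]` text analysis, a word
  planted in a background that uses the full alphabet can fail at the
  pair level because its letter pairs are common — asserted as a
  property test.
* **Chance-pattern counts are overdispersed.** One chance alignment
  spawns a family of decorated variants across passes, so per-length
  counts on pure noise have heavy tails. Consequently the mean+3SD
  band of 20 shuffle surrogates contains the observed per-length counts
  in about 90% of seeds at the calibration scale above, not 95%+: a
  singleton chance pattern can face a degenerate all-zero surrogate
  band, and a cluster can exceed a non-degenerate one. Tightening the
  selection adjustment until this exceeds 95% removes two-occurrence
  detectability; the trade-off is resolved in favor of sensitivity,
  with surrogate comparison kept as the global context for any
  observed count.
* **No substitutes/alternatives at pattern positions** — each variant
  is a different pattern; no trinary or higher trees; no automatic
  significance-level selection; no interactive visualization (static
  DOT trees and JSON point maps instead).
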
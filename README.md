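# tpattern

T-pattern detection and analysis for time-stamped categorical event
series — behavioral codings, interaction records, spike-like point
series, or (via a restricted mode) plain text and molecular sequences.

Behavior streams are coded as *T-data*: a discrete observation period
`[1, T]` and one occurrence-point series per categorical *event-type*
(e.g. `x,b,look` — individual *x* begins looking). Hidden structure in
such data often takes the form of a **T-pattern**

```
Q :  X1 [d1,d2]1 X2 [d1,d2]2 ... X(m-1) [d1,d2](m-1) Xm
```

an ordered set of m components that recurs such that each consecutive
distance falls within a component-pair-specific **critical interval**
`[d1, d2]` significantly more often than expected if the components were
placed independently at random. For two series A and B, a window of `w`
time units contains at least one of B's `N_B` points with null
probability `p0 = 1 - (1 - N_B/T)^w`; the number of A points followed by
a B point within `[a+d1, a+d2]` is then binomial, and an interval is
*critical* when the exact upper tail of the observed hit count clears
the significance level (default α = 0.005) after adjusting for the
interval search. Detection is bottom-up: significant pairs of series
become new working series, so pairs of pairs assemble a binary tree —
patterns of patterns — while a *completeness competition* discards
partial detections that a more complete pattern already accounts for.
Because many tests are performed, detected counts are validated per
length against **shuffling** (uniform redraw of each series) and
**rotation** (circular shift of each series) surrogates.

Two restricted modes: **T-bursts** (fast interval `[0, d2]` of a series
against itself — significant dense runs) and **[1,1]-restricted
patterns** over letter series, which assemble recurrent contiguous
strings such as words in blank-stripped text or motifs in sequences.

## Worked example

Recovering a 21-letter string planted twice in a 10,103-letter random
background (`examples/find_words_in_text.py`):

```
text of 10103 letters; word planted at positions [654, 2119]

2 recurrent strings found:
  ofthecomediefrancaise    length=21 n=2
  xg                       length=2 n=83

full word recovered: True
```

The word's letters occur only inside its two copies, so every adjacent
letter pair recurs exactly twice with distance 1; the `[1,1]` search
chains pairs into fours, eights, and finally the complete 21-terminal
pattern, while the competition absorbs all partial substrings. (`xg` is
a chance digram of the background — 83 adjacent occurrences where about
60 were expected.) Surrogate validation puts such detections in context
(`examples/validate_with_surrogates.py`):

```
length  observed  surrogate_mean  surrogate_sd
     2         0            0.25          0.43
     3         1            0.15          0.48  <-- planted length
     4         0            0.05          0.22

observed count at length 3 exceeds surrogate mean + 1 SD: True
```

The other examples cover detection in noisy multi-series T-data
(`detect_planted_pattern.py`), per-pattern statistics, selection and
inventory (`analyze_patterns.py`), and burst detection
(`detect_bursts.py`).

## Command line

A thin `tpa` CLI wraps the library for file-based workflows:

```bash
tpa simulate --plant-labels A,B,C --plant-gaps 5,7 --plant-k 4 --out demo.txt
tpa detect demo.txt --out-dir out/            # pattern table + manifest
tpa validate demo.txt --method shuffle --n 50 --seed 1 --out-dir out/
tpa sequence text.txt --n-min 2 --max-length 21   # [1,1] word search
tpa stats demo.txt / tpa select demo.txt --require A --ordered
tpa diagram demo.txt --index 0 --out pattern      # DOT tree + JSON map
```

Inputs are two-column tab-separated files (`<time><TAB><event-type>`),
one row per occurrence; several files are concatenated into a
multi-sample analysis. FASTA and plain text feed the sequence mode.

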
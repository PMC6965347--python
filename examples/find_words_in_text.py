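"""Recover a recurrent word from letter series with [1,1]-restricted patterns.

A text becomes T-data by giving every letter its own occurrence-point
series (position i of letter s is point i of series s). With the critical
interval fixed to [1,1], detected patterns are recurrent contiguous
strings, assembled bottom-up: pairs of letters, then pairs of pairs, and
so on. Here a 21-letter string is planted twice in a 10,103-letter random
background whose letters avoid the word's letters, isolating the
recurrence signal.
"""

from tpattern import (
    DetectionParams,
    detect_tpatterns,
    generate_text_with_plants,
    sequence_to_tdata,
)

WORD = "ofthecomediefrancaise"
text, positions = generate_text_with_plants(
    length=10_103,
    alphabet="abcdefghijklmnopqrstuvwxyz",
    word=WORD,
    k=2,
    background_excludes_word_letters=True,
    seed=7,
)
print(f"text of {len(text)} letters; word planted at positions {positions}")

data = sequence_to_tdata(text)
params = DetectionParams(
    alpha=0.005, n_min=2, mode="fixed_11", max_length=len(WORD), max_levels=12
)
patterns = detect_tpatterns(data, params)

print(f"\n{len(patterns)} recurrent strings found:")
for p in patterns:
    print(f"  {''.join(p.terminal_labels):<24} length={p.m} n={p.n}")

print("\nfull word recovered:", any("".join(p.terminal_labels) == WORD for p in patterns))
# Two occurrences suffice: each adjacent letter pair recurs twice, the
# pairs chain into fours, and the competition discards the partial
# substrings absorbed by the complete 21-letter pattern.
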
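"""Post-detection analysis: per-pattern statistics, selection, inventory.

Event-type labels follow the 'actor,phase,behavior' convention (x and y
are two individuals; b/e mark beginnings and ends), so actor counts and
switches between actors quantify how interactive a pattern is.
"""

import io
import sys

from tpattern import (
    DetectionParams,
    PatternTemplate,
    TData,
    detect_tpatterns,
    event_type_inventory,
    export_pattern_table,
    pattern_stats,
    plant_pattern,
    select_patterns,
)

base = TData(T=10_000, series=[])
data, _ = plant_pattern(
    base,
    PatternTemplate(labels=("x,b,pick", "y,b,take", "x,e,look"), gaps=(5, 7), k=4),
    seed=11,
    noise_points=8,
)
patterns = detect_tpatterns(data, DetectionParams())

print("per-pattern statistics:")
for p in patterns:
    st = pattern_stats(p)
    print(
        f"  {p.label():<45} n={st.n} actors={st.n_actors} "
        f"switches={st.actor_switches} mean_span={st.mean_span:.1f}"
    )

interactive = select_patterns(patterns, multi_actor_only=True)
print(f"\nmulti-actor (interaction) patterns: {len(interactive)} of {len(patterns)}")

print("\nevent-type inventory (first hierarchical level of appearance):")
for et, level in event_type_inventory(patterns):
    print(f"  {et.label:<12} level {level}")

buf = io.StringIO()
export_pattern_table(patterns, buf)
sys.stdout.write("\npattern table (TSV):\n" + buf.getvalue())
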
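"""Step-by-step: from unbroken routing to a cloneable scaffold sequence.

Shows the individual stages the search composes: trace the routing, cut a
random staple layout, assign one sequence per group, derive the forced-
complementary scaffold, screen it for BtsCI sites, and flank it with
cloning adapters.
"""

import random

from restaple import (
    DesignConfig,
    assign_sequences,
    count_motif,
    derive_scaffold,
    draw_layout,
    duplex_toy,
    flank_with_adapters,
    repeat_coverage,
    trace_scaffold,
    trace_staples,
)

design = duplex_toy()
scaffold_path = trace_scaffold(design)
unbroken = trace_staples(design)
print(f"routing: scaffold {len(scaffold_path)} nt, "
      f"{len(unbroken)} unbroken staple path(s)")

config = DesignConfig(k_unique=2, len_min=32, len_max=32, seed=0)
rng = random.Random(config.seed)
layout = draw_layout(unbroken, config, rng)
print(f"layout: {layout.staple_count} staples in {layout.k} groups, "
      f"lengths {[s.length for s in layout.staples]}")

seqs = assign_sequences(layout, config, rng)
scaffold = derive_scaffold(scaffold_path, layout, seqs, rng)
print(f"group sequences: {seqs.sequences}")
print(f"derived scaffold ({scaffold.length} nt): {scaffold.bases}")

report = repeat_coverage(scaffold.bases, window=12)
print(f"repeat coverage: {report.coverage_fraction:.3f} "
      "(every staple is used once here, so only chance repeats appear)")

for motif in ("GGATG", "CATCC"):
    print(f"BtsCI motif {motif}: {count_motif(scaffold.bases, motif)} hit(s) "
          "in the scaffold body (advisory; single-stranded sites cut poorly)")

insert = flank_with_adapters(scaffold, left="GCAGTGGATGCC", right="GGCATCCACTGC")
print(f"cloning insert with hairpin adapters: {len(insert)} nt")
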
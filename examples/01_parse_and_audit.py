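"""Parse a caDNAno design and audit its routing metrics.

Builds the smallest synthetic design (a two-helix duplex), writes it as
caDNAno v2 JSON, parses it back, and prints the design metrics a search
would be constrained by: scaffold length, staple routing and crossover
density per 1,000 scaffold nucleotides.
"""

from restaple import design_metrics, duplex_toy, parse_design, write_design

design = parse_design(write_design(duplex_toy()))
metrics = design_metrics(design)

print(f"design: {design.name} ({design.lattice_kind} lattice)")
print(f"scaffold length:    {metrics.scaffold_length} nt")
print(f"unbroken staples:   {metrics.staple_count}")
print(f"crossovers:         {metrics.scaffold_xovers} scaffold, "
      f"{metrics.staple_xovers} staple")
print(f"crossover density:  {metrics.xover_density:.2f} per 1,000 nt")
print()
print("A density around 30/1,000 is sparse (a toy duplex); dense 3D bundles"
      " run an order of magnitude higher.")
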
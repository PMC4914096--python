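# restaple

Design DNA-origami **custom scaffolds** that fold from a small set of
**reusable staple sequences**.

Standard scaffolded origami pins a long single-stranded scaffold (usually
M13mp18) into shape with ~150–250 staple oligonucleotides, each with a
unique sequence — and each unique sequence is a separate synthesis. If the
scaffold sequence is itself a design variable, the economics invert: choose
a handful of staple sequences, reuse each at many template locations, and
*derive* the scaffold as the forced Watson–Crick complement of the staples
laid onto the routing. A 6-kb, 24-helix bundle then needs as few as 10
unique staples, each binding ~10 template locations.

The price of reuse is repetition: a scaffold templated by few sequences is
repetitive, and repetitive DNA is hard to synthesize and folds worse.
restaple therefore treats design as a search problem:

1. read a caDNAno (v2 JSON) design whose staples are routed as long
   *unbroken* paths;
2. randomly cut the routing into staples (lengths drawn from a shared
   palette inside configurable bounds) and partition them into
   `k_unique` equal-length groups that will each share one sequence;
3. assign a random (or predefined) sequence per group and derive the
   complementary scaffold;
4. score the scaffold's **repeat coverage** — the fraction of nucleotides
   inside any 12-base window that occurs more than once — and
5. repeat for a library of layouts, rank ascending, and export the least
   repetitive candidate as a cross-validated caDNAno + FASTA + CSV set.

For calibration, M13mp18 scores ~2% by this metric, while reusable-staple
scaffolds land around 40–60% depending on how many unique sequences they
use.

## Worked example

```python
from restaple import DesignConfig, make_helix_bundle, run_search

design = make_helix_bundle(24, 6000, "honeycomb", 7)   # 24-helix, 6-kb bundle
config = DesignConfig(k_unique=10, iterations=20, seed=1)  # staples 38-77 nt
result = run_search(design, config)
for rank, c in enumerate(result.ranked[:3]):
    print(rank, c.index, f"{100*c.coverage:.1f}%", c.metrics.staple_count)
```

prints

```
0 7 63.0% 107
1 14 64.0% 100
2 6 64.8% 101
```

— the library's three least repetitive candidates: the winner's scaffold
has 63.0% of its nucleotides inside a duplicated 12-base window, folded by
107 staples drawn from 10 unique sequences (each bound at 10.7 template
locations on average). `export_result(result, out_dir)` writes the broken,
colour-coded caDNAno file, the scaffold FASTA, the unique-staple FASTA/CSV
and a report JSON, after re-parsing and re-hybridizing the files against
each other.

The `examples/` directory has one short script per capability (audit,
scoring, search, step-by-step scaffold derivation). The same functionality
is exposed as a thin CLI:

```sh
restaple design --cadnano design.json --k-unique 10 --preset bundle --out out/
restaple score scaffold.fasta --window 12 --bed covered.bed
restaple audit design.json
```

## Scope

restaple covers the computational design stage only: routing-file I/O,
layout search, sequence derivation, repetitiveness scoring and export.
Cloning, phage amplification, folding protocols and microscopy live in the
wet lab. caDNAno v2 is the only supported dialect; `skip` cells are
honoured, `loop` insertions are rejected. See `docs/methods.md` for the
model, parameter defaults and known limitations.
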
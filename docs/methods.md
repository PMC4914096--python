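# Methods

## The design problem

A scaffolded DNA-origami structure is specified in caDNAno as per-helix,
per-base linked lists for two antiparallel strand families: one long
scaffold and many short staples. restaple's input is such a design with the
staples still routed as long *unbroken* paths; its output is a concrete
design — staple break points, a grouping of staples into `k_unique`
sequence classes, one sequence per class, and the scaffold sequence forced
by complementarity — chosen to minimize scaffold repetitiveness.

Strand polarity follows the caDNAno convention: on even-numbered helices
the scaffold runs 5'→3' with increasing base index and staples with
decreasing index; odd helices are reversed. This convention is what
orients per-cell complementation: because scaffold and staple are
antiparallel through every cell, emitting the Watson–Crick complement of
the staple base at each scaffold-path position reproduces each staple's
reverse complement on the scaffold without any explicit reversal.

## Repeat coverage

Repetitiveness is the fraction of scaffold nucleotides covered by any
window of `window` bases (default 12) whose exact sequence occurs more than
once; every position of every occurrence of a duplicated window counts.
Scoring is forward-strand and linear: the scaffold handed to a folding
reaction is a linear single strand, and a repeat means the same strand
contains the same window twice. Reverse-complement-inclusive scoring is
available behind a flag for exploration but is never the default. Input is
case-folded; non-ACGT characters are rejected with their offset. The
implementation hashes windows (O(L·w)); its correctness oracle in the test
suite is a brute-force all-pairs window comparison, and the two must agree
exactly.

## Layout search

Each search draw is independent and fully determined by `(seed, draw
index)` (streams are seeded as `"{seed}:{i}"`, so draws can be reordered or
parallelized without changing results):

1. **Palette segmentation.** A palette of at most `k_unique` distinct
   staple lengths (default palette size ⌈k/2⌉) is sampled uniformly from
   `[len_min, len_max]`; each unbroken path is cut into a random exact
   composition of palette lengths. Feasibility is pre-computed with a
   subset-sum bitset, so the randomized walk never dead-ends; if some path
   admits no composition the palette is redrawn (budget 100).
2. **Grouping.** Staples are classed by length; `k_unique` groups are
   apportioned to classes by largest remainder and membership within a
   class is randomized. Groups must be length-homogeneous because all
   members share one sequence. Using fewer distinct lengths than groups
   leaves room to split classes into near-equal groups, which is why the
   palette default is ⌈k/2⌉.
3. **Balance.** Layouts whose group sizes stray more than
   `multiplicity_tol` (default 2) from the balanced value
   `staple_count / k_unique` are rejected and redrawn (budget 100). This is
   a soft constraint: hard enforcement can make small designs infeasible.
4. **Sequences and scaffold.** One i.i.d.-uniform random sequence per group
   (optional GC bounds by rejection; optional predefined sequences matched
   to groups by length), then per-cell complementation along the scaffold
   path. Scaffold positions not covered by any staple are filled from the
   seeded stream and recorded; they are scored like every other position.
5. **Scoring and ranking.** Candidates are ranked by ascending coverage,
   ties broken by draw index. Infeasible draws are recorded with reasons
   and excluded; only a search with zero feasible draws errors.

An optional *repetitive arrangement* mode reproduces the design class in
which a reused staple crosses helices at identical offsets everywhere it
binds: a single staple length dividing every unbroken path is forced, and
groups are additionally signature-homogeneous. This mode exists to study
the (worse-folding) repetitive-crossover regime, not as a default.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `k_unique` | — | unique staple sequences (10–20 for the 6-kb bundle) |
| `len_min, len_max` | 38, 77 nt | staple length bounds; presets `short` 25–62, `long` 60–125, `bundle` 38–77 |
| `window` | 12 nt | minimum repeat length for the coverage metric |
| `iterations` | 100 | library size (layout draws per search) |
| `n_best` | 1 | candidates exported |
| `multiplicity_tol` | 2 | allowed deviation of group sizes from the balanced value |
| `gc_min, gc_max` | off | GC bounds for random sequences |
| `forbidden_motifs` | GGATG, CATCC | advisory screen (BtsCI site and reverse complement); hits are warned, never fatal |

BtsCI hits on the single-stranded scaffold body are advisory because the
enzyme strongly prefers double-stranded sites — the double-stranded hairpin
adapters that release the scaffold after phage amplification are the
intended cut sites. Adapter sequences are user-supplied
(`flank_with_adapters`).

## Synthetic fixtures

`make_helix_bundle(n, L, lattice, step)` generates a connected n-helix
design on a chain of virtual helices: the scaffold is a horizontal
serpentine raster (one linear strand, crossing between neighbours at the
ends of the occupied region), and the staple routing is a set of unbroken
vertical column serpentines. Honeycomb column widths alternate 2× and 1×
the permitted-crossover step (14/7 nt at the default step of 7), which
makes within-helix staple segments alternate 14 and 7 nt — the dense end of
the honeycomb crossover raster, emulating the high-staple-crossover-density
class used for large reusable-staple bundles. Square lattices use a
constant 2× column (the 2-helix "duplex toy" is one 32-nt column: one
scaffold and one staple crossover, density 31.25 per 1,000 nt). Array
lengths are padded to caDNAno granularity (21 honeycomb / 32 square), and
the scaffold length lands within 2% of the requested target. Generation is
deterministic.

What the fixtures do *not* emulate: a real 24-helix bundle has a
two-dimensional honeycomb cross-section in which each helix couples to up
to three neighbours with crossover phases staggered by 7 nt. The chain
fixture gives every helix exactly two neighbour pairs, so the fraction of
positions lying in staple segments long enough to host a 12-nt window is
structurally 2/3 — slightly higher than in three-neighbour routings. In
practice this biases best-of-library repeat coverage a few points upward
relative to hand-routed bundles of the same size (we measure ~62% at
k = 10 and ~42% at k = 20 on the fixture, versus ~56%/39% reported for
comparable hand-routed designs); the ordering and scale of the k-dependence
are unaffected. A dense scaffold-crossover raster was also evaluated for
the fixture and rejected: in a perfectly aligned chain every relative phase
of a 21-nt scaffold raster either coincides with staple crossovers
(impossible in a real design and inflates repeats), systematically chops
every staple domain (the metric stops seeing reuse), or shadows the short
staple bands (manufactures junction repeats); the plain raster is the only
artifact-free choice at this level of abstraction.

Problem sizes in the test suite and acceptance script follow the designs
they emulate: a 24-helix, 6,000-nt fixture; 20-draw libraries where a
library statistic (multiplicity, length bounds) is checked; the default
100-draw libraries where best-of-library repetitiveness is compared.

## Numerical and degenerate-input choices

- Tracing honours `skip = -1` (base omitted from paths and lengths); `loop`
  insertions are rejected as unsupported rather than silently misindexed.
- Circular strands are traced from their lowest (helix, index) position;
  circular unbroken staple paths are opened at that position before
  segmentation. Crossover counts treat circular strands like linear ones
  (no wraparound adjacency), and the repeat metric never wraps.
- A crossover is one helix-change adjacency in one strand path; a double
  crossover therefore counts twice, once per strand. Crossover density is
  per 1,000 scaffold nucleotides. Published crossover-density figures for
  comparable designs use an unstated convention, so no attempt is made to
  reproduce them numerically.
- Sequences are compared and stored uppercase; ties in group assignment are
  broken by the seeded stream, never by input order.
- Exports are byte-stable: stable JSON field order, no timestamps; a
  re-export with the same (design, config, seed) is byte-identical.

## Known limitations

- caDNAno v2 only; scadnano and caDNAno 2.5 files are rejected with a clear
  message. Multi-scaffold designs are rejected at search time.
- No thermodynamics: break placement ignores seam stability, melting
  temperatures and secondary structure; the only objective is repeat
  coverage.
- The repeat metric is sequence-exact; it does not model near-repeats or
  synthesis chemistry beyond exact-window duplication.
- The chain fixtures approximate, but do not reproduce, hand-routed
  honeycomb bundles (see above); conclusions about absolute repetitiveness
  of real shapes should be drawn from real caDNAno files, which the tool
  accepts directly.
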
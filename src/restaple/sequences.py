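"""Assign sequences to staple groups and derive the complementary scaffold.

Every staple in a group carries the same sequence (random or predefined).
The custom scaffold sequence is then *forced*: at each scaffold position the
base is the Watson–Crick complement of the staple base hybridized at the
same lattice cell. Because scaffold and staple run antiparallel through a
cell, per-cell complementation automatically produces the reverse
complement of each staple along the scaffold. Scaffold positions no staple
covers are filled from the seeded random stream and recorded.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import DesignConfig
from .errors import ConsistencyError, GenerationError, SequenceAssignmentError
from .layout import StapleLayout
from .strands import StrandPath

__all__ = [
    "SequenceSet",
    "ScaffoldSequence",
    "random_sequence",
    "assign_sequences",
    "derive_scaffold",
    "count_motif",
    "flank_with_adapters",
    "COMPLEMENT",
]

logger = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

GC_RETRIES = 1000


@dataclass(frozen=True)
class SequenceSet:
    """One base string per staple group, plus where the strings came from."""

    sequences: tuple[str, ...]  # indexed by group id
    provenance: str  # "random" | "predefined"

    def __getitem__(self, gid: int) -> str:
        return self.sequences[gid]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class ScaffoldSequence:
    """The derived scaffold: bases along the scaffold path, 5'→3'."""

    bases: str
    unpaired_positions: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return len(self.bases)


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_sequence(length: int, config: DesignConfig, rng: random.Random) -> str:
    """An i.i.d.-uniform base string, resampled into the configured GC
    bounds when those are set. Deterministic for a given rng state."""
    if length < 1:
        raise ValueError(f"sequence length must be >= 1, got {length}")
    for _ in range(GC_RETRIES):
        seq = "".join(rng.choice(BASES) for _ in range(length))
        if config.gc_min is None:
            return seq
        if config.gc_min <= _gc_fraction(seq) <= config.gc_max:
            return seq
    raise GenerationError(
        f"no {length}-mer within GC bounds [{config.gc_min}, {config.gc_max}] "
        f"after {GC_RETRIES} draws"
    )


def assign_sequences(
    layout: StapleLayout, config: DesignConfig, rng: random.Random
) -> SequenceSet:
    """One sequence per group.

    Predefined mode: the configured sequences are used verbatim, matched to
    groups by length (every length mismatch or a count != k_unique is an
    error). Random mode: one fresh random sequence per group, redrawn on
    the (unlikely) collision so the k sequences are distinct.
    """
    group_lengths = [layout.group_length(g) for g in range(layout.k)]
    if config.sequences is not None:
        provided = list(config.sequences)
        if len(provided) != layout.k:
            raise SequenceAssignmentError(
                f"{len(provided)} predefined sequences for k_unique={layout.k}"
            )
        bad = [s for s in provided if set(s) - set(BASES)]
        if bad:
            raise SequenceAssignmentError(
                f"non-ACGT characters in predefined sequences: {bad}"
            )
        pool: dict[int, list[str]] = {}
        for seq in provided:
            pool.setdefault(len(seq), []).append(seq)
        chosen: list[str] = []
        missing: list[int] = []
        for length in group_lengths:
            if pool.get(length):
                chosen.append(pool[length].pop())
            else:
                missing.append(length)
        if missing:
            leftover = [s for lst in pool.values() for s in lst]
            raise SequenceAssignmentError(
                f"no predefined sequence of length(s) {missing}; "
                f"unused entries with lengths {[len(s) for s in leftover]}"
            )
        return SequenceSet(sequences=tuple(chosen), provenance="predefined")

    seqs: list[str] = []
    seen: set[str] = set()
    for length in group_lengths:
        seq = random_sequence(length, config, rng)
        while seq in seen:
            seq = random_sequence(length, config, rng)
        seen.add(seq)
        seqs.append(seq)
    return SequenceSet(sequences=tuple(seqs), provenance="random")


def derive_scaffold(
    scaffold_path: StrandPath,
    layout: StapleLayout,
    seqs: SequenceSet,
    rng: random.Random,
) -> ScaffoldSequence:
    """Walk the scaffold path and emit, at every position, the complement
    of the staple base occupying the same (helix, idx) cell.

    Positions with no staple coverage are filled from the seeded stream and
    recorded in ``unpaired_positions``. Two staples claiming one cell raise
    :class:`ConsistencyError` (impossible for a valid layout).
    """
    cell_base: dict[tuple[int, int], str] = {}
    for staple, gid in zip(layout.staples, layout.group_of):
        seq = seqs[gid]
        for offset, cell in enumerate(staple.path.positions):
            if cell in cell_base:
                raise ConsistencyError(
                    f"two staples claim cell {cell}; layout is overlapping"
                )
            cell_base[cell] = seq[offset]

    bases: list[str] = []
    unpaired: list[int] = []
    for offset, cell in enumerate(scaffold_path.positions):
        staple_base = cell_base.get(cell)
        if staple_base is None:
            bases.append(rng.choice(BASES))
            unpaired.append(offset)
        else:
            bases.append(COMPLEMENT[staple_base])
    return ScaffoldSequence(
        bases="".join(bases), unpaired_positions=tuple(unpaired)
    )


def count_motif(seq: str, motif: str) -> int:
    """Count overlapping occurrences of ``motif`` on the given strand.

    Call again with the motif's reverse complement to cover the other
    strand.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = seq.upper()
    motif = motif.upper()
    count = 0
    start = seq.find(motif)
    while start != -1:
        count += 1
        start = seq.find(motif, start + 1)
    return count


def flank_with_adapters(
    scaffold: ScaffoldSequence | str,
    left: str,
    right: str,
    forbidden_motifs: Sequence[str] = (),
) -> str:
    """Concatenate cloning adapters around the scaffold body.

    The adapters typically encode the hairpins whose double-stranded
    restriction sites release the scaffold after phage amplification.
    Forbidden-motif hits *inside the scaffold body* are counted and logged
    as a warning — advisory only, never an error.
    """
    body = scaffold.bases if isinstance(scaffold, ScaffoldSequence) else scaffold
    for name, adapter in (("left", left), ("right", right)):
        if set(adapter.upper()) - set(BASES):
            raise ValueError(f"non-ACGT characters in {name} adapter")
    hits = sum(count_motif(body, m) for m in forbidden_motifs if m)
    if hits:
        logger.warning(
            "scaffold body contains %d forbidden-motif hit(s) (%s)",
            hits,
            ",".join(forbidden_motifs),
        )
    return left.upper() + body + right.upper()
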
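"""Randomized staple layout generation.

The input design routes its staples as long *unbroken* paths. A layout is
(1) a segmentation of each unbroken path into consecutive staples and (2) a
partition of the staples into ``k_unique`` groups that will each receive a
single sequence. Because every member of a group shares one sequence, all
staples in a group must have the same length.

Segmentation is palette-based: a palette of at most ``k_unique`` distinct
lengths within ``[len_min, len_max]`` is drawn, and each unbroken path is
cut into a random exact composition of palette lengths (feasibility is
checked with a subset-sum table, so the random walk never dead-ends).
Grouping splits each length class into near-equal groups apportioned by
class size; a layout whose group sizes stray more than ``multiplicity_tol``
from the balanced value ``staple_count / k_unique`` is rejected and redrawn.

An optional *repetitive arrangement* mode reproduces the design class in
which reused staples cross helices at identical offsets: it forces a single
staple length that divides every unbroken path and groups staples by
crossover signature, so same-group staples have identical signatures.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import DesignConfig
from .errors import LayoutInfeasibleError
from .strands import StrandPath, crossover_offsets

__all__ = [
    "Staple",
    "StapleLayout",
    "segment_paths",
    "assign_groups",
    "draw_layout",
    "validate_layout",
]

PALETTE_RETRIES = 100
LAYOUT_RETRIES = 100


@dataclass(frozen=True)
class Staple:
    """One staple: its path, length and crossover-offset signature."""

    path: StrandPath
    length: int
    signature: tuple[int, ...]

    @classmethod
    def from_path(cls, path: StrandPath) -> "Staple":
        return cls(
            path=path, length=len(path), signature=tuple(crossover_offsets(path))
        )


@dataclass(frozen=True)
class StapleLayout:
    """A segmentation of the unbroken routing plus a k-group partition."""

    staples: tuple[Staple, ...]
    group_of: tuple[int, ...]  # staple index -> group id in [0, k)
    k: int
    source_paths: tuple[StrandPath, ...] = field(default=(), compare=False)

    @property
    def groups(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {g: [] for g in range(self.k)}
        for idx, g in enumerate(self.group_of):
            out[g].append(idx)
        return out

    def group_length(self, gid: int) -> int:
        members = self.groups[gid]
        return self.staples[members[0]].length if members else 0

    @property
    def staple_count(self) -> int:
        return len(self.staples)


def _feasible_sums(length: int, palette: Sequence[int]) -> int:
    """Bitset of sums reachable with unlimited copies of palette lengths."""
    feas = 1  # bit v set <=> v is a reachable sum
    for v in range(min(palette), length + 1):
        for p in palette:
            if v >= p and (feas >> (v - p)) & 1:
                feas |= 1 << v
                break
    return feas


def _compose(length: int, palette: Sequence[int], rng: random.Random) -> Optional[list[int]]:
    """Random exact composition of ``length`` from palette lengths, or None."""
    feas = _feasible_sums(length, palette)
    if not (feas >> length) & 1:
        return None
    cuts: list[int] = []
    rem = length
    while rem:
        choices = [p for p in palette if rem >= p and (feas >> (rem - p)) & 1]
        cuts.append(rng.choice(choices))
        rem -= cuts[-1]
    return cuts


def _cut_path(path: StrandPath, cuts: Sequence[int]) -> list[Staple]:
    staples = []
    start = 0
    for length in cuts:
        sub = StrandPath(
            kind="staple",
            positions=path.positions[start : start + length],
            circular=False,
        )
        staples.append(Staple.from_path(sub))
        start += length
    return staples


def _draw_palette(config: DesignConfig, rng: random.Random) -> list[int]:
    lengths = range(config.len_min, config.len_max + 1)
    return sorted(rng.sample(lengths, config.effective_palette_size))


def segment_paths(
    unbroken: Sequence[StrandPath],
    config: DesignConfig,
    rng: random.Random,
    palette: Optional[Sequence[int]] = None,
) -> list[Staple]:
    """Cut each unbroken staple path into consecutive staples whose lengths
    come from one shared palette of at most ``k_unique`` distinct lengths.

    A circular unbroken path is opened at its stored start position. When no
    palette is forced, fresh random palettes are drawn until every path has
    an exact composition (up to a bounded retry budget).
    """
    for path in unbroken:
        if len(path) < config.len_min:
            raise LayoutInfeasibleError(
                f"unbroken path starting at {path.positions[0]} has length "
                f"{len(path)} < len_min {config.len_min}"
            )
    palettes = (
        [list(palette)]
        if palette is not None
        else (_draw_palette(config, rng) for _ in range(PALETTE_RETRIES))
    )
    last_bad: Optional[StrandPath] = None
    for pal in palettes:
        if len(set(pal)) > config.k_unique:
            raise LayoutInfeasibleError(
                f"palette {sorted(set(pal))} has more than k_unique="
                f"{config.k_unique} distinct lengths"
            )
        staples: list[Staple] = []
        ok = True
        for path in unbroken:
            cuts = _compose(len(path), pal, rng)
            if cuts is None:
                ok = False
                last_bad = path
                break
            staples.extend(_cut_path(path, cuts))
        if ok:
            return staples
    assert last_bad is not None
    raise LayoutInfeasibleError(
        f"no palette partitioned the path starting at {last_bad.positions[0]} "
        f"(length {len(last_bad)}) within the retry budget"
    )


def _apportion(class_sizes: list[int], k: int) -> list[int]:
    """Hamilton (largest-remainder) apportionment of k groups to length
    classes, at least one and at most ``size`` groups per class."""
    total = sum(class_sizes)
    quotas = [k * s / total for s in class_sizes]
    counts = [max(1, min(int(q), s)) for q, s in zip(quotas, class_sizes)]
    # distribute the remainder by largest fractional part, respecting caps
    while sum(counts) < k:
        best = max(
            (i for i in range(len(counts)) if counts[i] < class_sizes[i]),
            key=lambda i: quotas[i] - counts[i],
            default=None,
        )
        if best is None:
            break
        counts[best] += 1
    while sum(counts) > k:
        worst = min(
            (i for i in range(len(counts)) if counts[i] > 1),
            key=lambda i: quotas[i] - counts[i],
            default=None,
        )
        if worst is None:
            break
        counts[worst] -= 1
    return counts


def assign_groups(
    staples: Sequence[Staple],
    config: DesignConfig,
    rng: random.Random,
    by_signature: bool = False,
) -> StapleLayout:
    """Partition staples into exactly ``k_unique`` length-homogeneous,
    non-empty groups, randomizing membership among equal-length staples.

    With ``by_signature`` (the repetitive-arrangement mode), staples are
    classed by ``(length, signature)`` so each group is also
    signature-homogeneous.
    """
    k = config.k_unique
    if len(staples) < k:
        raise LayoutInfeasibleError(
            f"{len(staples)} staples cannot form {k} non-empty groups"
        )
    classes: dict[object, list[int]] = {}
    for idx, st in enumerate(staples):
        key = (st.length, st.signature) if by_signature else st.length
        classes.setdefault(key, []).append(idx)
    if len(classes) > k:
        raise LayoutInfeasibleError(
            f"{len(classes)} staple classes cannot be merged into {k} "
            "homogeneous groups"
        )
    keys = sorted(classes)
    sizes = [len(classes[key]) for key in keys]
    counts = _apportion(sizes, k)
    if sum(counts) != k:
        raise LayoutInfeasibleError(
            "no length-homogeneous partition into k non-empty groups exists"
        )

    group_of = [0] * len(staples)
    gid = 0
    for key, g in zip(keys, counts):
        members = list(classes[key])
        rng.shuffle(members)
        base, extra = divmod(len(members), g)
        start = 0
        for j in range(g):
            size = base + (1 if j < extra else 0)
            for idx in members[start : start + size]:
                group_of[idx] = gid
            start += size
            gid += 1
    return StapleLayout(
        staples=tuple(staples), group_of=tuple(group_of), k=k
    )


def _balanced(layout: StapleLayout, tol: int) -> bool:
    target = layout.staple_count / layout.k
    return all(
        abs(len(members) - target) <= tol for members in layout.groups.values()
    )


def _divisor_palette(
    unbroken: Sequence[StrandPath], config: DesignConfig
) -> list[int]:
    """Single-length palettes for the repetitive-arrangement mode: lengths
    dividing every unbroken path, so cuts align with the crossover raster."""
    candidates = [
        length
        for length in range(config.len_min, config.len_max + 1)
        if all(len(p) % length == 0 for p in unbroken)
    ]
    if not candidates:
        raise LayoutInfeasibleError(
            "repetitive arrangement needs one staple length dividing every "
            "unbroken path; none exists in the configured length bounds"
        )
    return candidates


def draw_layout(
    unbroken: Sequence[StrandPath], config: DesignConfig, rng: random.Random
) -> StapleLayout:
    """One full random layout draw: segment, group, and enforce the
    balanced-multiplicity tolerance by rejection, within a retry budget."""
    reasons: list[str] = []
    for _ in range(LAYOUT_RETRIES):
        try:
            if config.repetitive_arrangement:
                length = rng.choice(_divisor_palette(unbroken, config))
                staples = segment_paths(unbroken, config, rng, palette=[length])
                layout = assign_groups(staples, config, rng, by_signature=True)
            else:
                staples = segment_paths(unbroken, config, rng)
                layout = assign_groups(staples, config, rng)
        except LayoutInfeasibleError as exc:
            reasons.append(str(exc))
            continue
        if _balanced(layout, config.multiplicity_tol):
            return StapleLayout(
                staples=layout.staples,
                group_of=layout.group_of,
                k=layout.k,
                source_paths=tuple(unbroken),
            )
        reasons.append("group sizes outside multiplicity tolerance")
    detail = reasons[-1] if reasons else "no attempts recorded"
    raise LayoutInfeasibleError(
        f"no acceptable layout in {LAYOUT_RETRIES} attempts (last: {detail})"
    )


def validate_layout(layout: StapleLayout, config: DesignConfig) -> list[str]:
    """Check a layout against the config; violations are data, not errors.

    Returns an empty list iff all staple lengths are within bounds, every
    group is non-empty and length-homogeneous, and (when the layout records
    its source paths) the staples partition each unbroken path exactly.
    """
    violations: list[str] = []
    for idx, st in enumerate(layout.staples):
        if not (config.len_min <= st.length <= config.len_max):
            violations.append(
                f"staple {idx}: length {st.length} outside "
                f"[{config.len_min}, {config.len_max}]"
            )
        if st.length != len(st.path):
            violations.append(f"staple {idx}: length field disagrees with path")
    for gid, members in layout.groups.items():
        if not members:
            violations.append(f"group {gid}: empty")
            continue
        lengths = {layout.staples[i].length for i in members}
        if len(lengths) > 1:
            violations.append(
                f"group {gid}: mixes staple lengths {sorted(lengths)}"
            )
    if len(layout.group_of) != len(layout.staples):
        violations.append("group_of does not map every staple")
    if layout.source_paths:
        flat: list[tuple[int, int]] = []
        for st in layout.staples:
            flat.extend(st.path.positions)
        source: list[tuple[int, int]] = []
        for p in layout.source_paths:
            source.extend(p.positions)
        if flat != source:
            violations.append("staples do not partition the unbroken routing")
    return violations
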
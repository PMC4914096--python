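"""Trace scaffold and staple strand paths and compute design metrics.

A strand path is the ordered 5'→3' list of ``(helix_num, base_idx)``
positions a strand occupies. Adjacent positions either step along one helix
(idx ± 1) or change helix — a *crossover*. Crossover density is reported
per 1,000 scaffold nucleotides, counting every helix-change adjacency in
every strand path once (so a double crossover counts twice, once per
strand). Skipped bases (caDNAno ``skip == -1``) are excluded from paths and
from all lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

from .cadnano import LatticeDesign
from .errors import ConsistencyError, TopologyError

if TYPE_CHECKING:  # pragma: no cover
    from .layout import StapleLayout

__all__ = [
    "StrandPath",
    "DesignMetrics",
    "trace_scaffold",
    "trace_staples",
    "crossover_offsets",
    "design_metrics",
]


@dataclass(frozen=True)
class StrandPath:
    """An ordered 5'→3' walk of one strand through the lattice."""

    kind: str  # "scaffold" | "staple"
    positions: tuple[tuple[int, int], ...]
    circular: bool = False

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def crossover_count(self) -> int:
        return len(crossover_offsets(self))

    def segments(self) -> list[tuple[int, int, int]]:
        """Within-helix runs as ``(helix, first_idx, last_idx)`` in path order."""
        runs: list[tuple[int, int, int]] = []
        for h, i in self.positions:
            if runs and runs[-1][0] == h and abs(runs[-1][2] - i) == 1:
                runs[-1] = (h, runs[-1][1], i)
            else:
                runs.append((h, i, i))
        return runs


def crossover_offsets(path: StrandPath) -> list[int]:
    """Offsets ``o`` (1 <= o < len) where the strand changes helix between
    positions ``o-1`` and ``o``. Used as a staple's arrangement signature."""
    return [
        o
        for o in range(1, len(path.positions))
        if path.positions[o - 1][0] != path.positions[o][0]
    ]


def _link_maps(design: LatticeDesign, kind: str):
    """Per-cell next/prev pointer maps and the set of non-skipped cells."""
    attr = "scaf" if kind == "scaffold" else "stap"
    nxt: dict[tuple[int, int], Optional[tuple[int, int]]] = {}
    prv: dict[tuple[int, int], Optional[tuple[int, int]]] = {}
    emit: set[tuple[int, int]] = set()
    for helix in design.helices:
        arr = getattr(helix, attr)
        for idx, cell in enumerate(arr):
            if cell.is_empty:
                continue
            pos = (helix.num, idx)
            nxt[pos] = (cell.next_helix, cell.next_idx) if cell.has_next else None
            prv[pos] = (cell.prev_helix, cell.prev_idx) if cell.has_prev else None
            if helix.skip[idx] != -1:
                emit.add(pos)
    return nxt, prv, emit


def _walk(start, nxt, emit, stop_at_start: bool) -> tuple[int, ...]:
    positions = []
    seen = set()
    pos = start
    while pos is not None and pos not in seen:
        seen.add(pos)
        if pos in emit:
            positions.append(pos)
        pos = nxt[pos]
        if stop_at_start and pos == start:
            break
    return tuple(positions), seen


def _trace(design: LatticeDesign, kind: str) -> list[StrandPath]:
    nxt, prv, emit = _link_maps(design, kind)
    visited: set[tuple[int, int]] = set()
    paths: list[StrandPath] = []

    five_primes = sorted(p for p in nxt if prv[p] is None)
    for start in five_primes:
        positions, seen = _walk(start, nxt, emit, stop_at_start=False)
        visited |= seen
        paths.append(StrandPath(kind=kind, positions=positions, circular=False))

    # remaining occupied cells belong to circular components; start each at
    # its lowest (helix num, idx) position
    leftover = sorted(set(nxt) - visited)
    while leftover:
        start = leftover[0]
        positions, seen = _walk(start, nxt, emit, stop_at_start=True)
        visited |= seen
        paths.append(StrandPath(kind=kind, positions=positions, circular=True))
        leftover = sorted(set(nxt) - visited)
    return [p for p in paths if p.positions]


def trace_scaffold(design: LatticeDesign) -> StrandPath:
    """Return the single scaffold strand's full 5'→3' path.

    If the scaffold is circular the path starts at the lowest
    ``(helix num, idx)`` position and ``circular`` is True. A design with
    zero or several scaffold components raises :class:`TopologyError`.
    """
    paths = _trace(design, "scaffold")
    if len(paths) != 1:
        raise TopologyError(
            f"expected exactly 1 scaffold component, found {len(paths)}"
        )
    return paths[0]


def trace_staples(design: LatticeDesign) -> list[StrandPath]:
    """All staple paths: one per 5' terminus plus circular components
    (flagged). Together they cover every staple-occupied cell exactly once."""
    return _trace(design, "staple")


@dataclass(frozen=True)
class DesignMetrics:
    """Per-design summary statistics.

    ``xover_density`` is ``1000 * (scaffold_xovers + staple_xovers) /
    scaffold_length``. Multiplicity statistics (staples per unique sequence)
    are present only when a grouped layout is supplied.
    """

    scaffold_length: int
    staple_count: int
    unique_count: Optional[int]
    multiplicity_mean: Optional[float]
    multiplicity_sd: Optional[float]
    staple_len_min: int
    staple_len_max: int
    scaffold_xovers: int
    staple_xovers: int
    xover_density: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def design_metrics(
    design: LatticeDesign, layout: "Optional[StapleLayout]" = None
) -> DesignMetrics:
    """Compute crossover, length and multiplicity statistics.

    Without a layout, staple statistics describe the design's (possibly
    unbroken) staple paths as routed. With a layout, the layout's staples
    are used and must tile the design's staple-occupied cells exactly.
    """
    scaffold_paths = _trace(design, "scaffold")
    if layout is None:
        staple_paths = trace_staples(design)
        group_sizes = None
    else:
        staple_paths = [s.path for s in layout.staples]
        occupied = {(h, i) for h, i, _ in design.cells("staple")}
        covered: set[tuple[int, int]] = set()
        for p in staple_paths:
            covered.update(p.positions)
        if covered != occupied:
            raise ConsistencyError(
                "layout staples do not tile the design's staple cells "
                f"({len(covered)} layout cells vs {len(occupied)} design cells)"
            )
        group_sizes = [len(v) for v in layout.groups.values()]

    scaffold_xovers = sum(p.crossover_count for p in scaffold_paths)
    staple_xovers = sum(p.crossover_count for p in staple_paths)
    lengths = [len(p) for p in staple_paths]
    n_scaffold = sum(len(p) for p in scaffold_paths)

    if group_sizes:
        mean = sum(group_sizes) / len(group_sizes)
        sd = math.sqrt(sum((g - mean) ** 2 for g in group_sizes) / len(group_sizes))
        unique: Optional[int] = len(group_sizes)
    else:
        mean = sd = None  # type: ignore[assignment]
        unique = None

    return DesignMetrics(
        scaffold_length=n_scaffold,
        staple_count=len(staple_paths),
        unique_count=unique,
        multiplicity_mean=mean,
        multiplicity_sd=sd,
        staple_len_min=min(lengths) if lengths else 0,
        staple_len_max=max(lengths) if lengths else 0,
        scaffold_xovers=scaffold_xovers,
        staple_xovers=staple_xovers,
        xover_density=1000.0 * (scaffold_xovers + staple_xovers) / n_scaffold,
    )
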
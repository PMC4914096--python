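"""Synthetic caDNAno designs for testing and benchmarking.

:func:`make_helix_bundle` emits a connected n-helix bundle on a chain of
virtual helices: a single linear scaffold raster-routed through all helices
(serpentine, crossing between neighbours at the ends of the occupied
region) and *unbroken* staple paths running antiparallel, organised as
vertical column serpentines so staple crossovers are interleaved along
every helix.

Honeycomb geometry permits staple crossovers to a given neighbour every
three steps of the 7-nt raster; the fixtures use those positions densely,
which yields column widths alternating 2x and 1x the permitted step (14/7
nt for the default step of 7). This emulates the high-staple-crossover-
density design class used for the large reusable-staple bundles. Square
geometry uses a constant column width of twice the step. Fixture
generation is fully deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .cadnano import EMPTY_CELL, BaseCell, LatticeDesign, VirtualHelix, write_design
from .errors import FixtureError

__all__ = ["BundleSpec", "make_helix_bundle", "duplex_toy", "make_degenerate_cases"]

EDGE_PAD = 16  # unoccupied cells left of the used region
DEFAULT_COLOR = 13369344  # caDNAno red


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of a synthetic bundle."""

    n_helices: int
    scaffold_length: int  # approximate target, matched within 2%
    lattice_kind: str = "honeycomb"
    xover_spacing: int = 7  # permitted-crossover step, nt

    def __post_init__(self) -> None:
        if self.n_helices < 2:
            raise FixtureError("need at least 2 helices")
        if self.n_helices % 2:
            raise FixtureError("need an even helix count for a closed raster")
        if self.scaffold_length < self.n_helices * 8:
            raise FixtureError(
                f"scaffold_length {self.scaffold_length} < "
                f"{self.n_helices} helices x 8 nt"
            )
        if self.lattice_kind not in ("honeycomb", "square"):
            raise FixtureError(f"unknown lattice kind {self.lattice_kind!r}")
        if self.xover_spacing < 2:
            raise FixtureError("xover_spacing must be >= 2")


def _column_widths(m: int, spec: BundleSpec) -> list[int]:
    """Partition the occupied idx range into staple-column widths."""
    if spec.lattice_kind == "honeycomb":
        pattern = [2 * spec.xover_spacing, spec.xover_spacing]
    else:
        pattern = [2 * spec.xover_spacing]
    widths: list[int] = []
    rem = m
    i = 0
    while rem > 0:
        w = min(pattern[i % len(pattern)], rem)
        if rem - w < 4:  # absorb tiny tails into the last column
            w = rem
        widths.append(w)
        rem -= w
        i += 1
    return widths


def _set_links(arrays, path):
    """Write prev/next pointers for one strand path into per-helix arrays."""
    for a, b in zip(path, path[1:]):
        ha, ia = a
        hb, ib = b
        ca = arrays[ha][ia]
        arrays[ha][ia] = BaseCell(ca.prev_helix, ca.prev_idx, hb, ib)
        cb = arrays[hb][ib]
        arrays[hb][ib] = BaseCell(ha, ia, cb.next_helix, cb.next_idx)
    # mark termini as occupied even if they have a single link
    for h, i in (path[0], path[-1]):
        if arrays[h][i] == EMPTY_CELL:
            raise FixtureError("single-base strand is not representable")


def make_helix_bundle(
    spec: BundleSpec | int,
    scaffold_length: int | None = None,
    lattice_kind: str | None = None,
    xover_spacing: int | None = None,
) -> LatticeDesign:
    """Build a synthetic bundle design.

    Accepts a :class:`BundleSpec` or positional arguments
    ``(n_helices, scaffold_length[, lattice_kind[, xover_spacing]])``.
    Two-helix bundles default to square geometry with step 16 (the duplex
    toy); larger bundles default to honeycomb with step 7.
    """
    if not isinstance(spec, BundleSpec):
        n = int(spec)
        kind = lattice_kind or ("square" if n <= 2 else "honeycomb")
        step = xover_spacing or (16 if kind == "square" else 7)
        spec = BundleSpec(n, int(scaffold_length), kind, step)

    n = spec.n_helices
    m = round(spec.scaffold_length / n)
    if abs(n * m - spec.scaffold_length) > 0.02 * spec.scaffold_length:
        raise FixtureError(
            f"cannot hit scaffold length {spec.scaffold_length} within 2% "
            f"using {n} equal helices"
        )
    gran = 21 if spec.lattice_kind == "honeycomb" else 32
    array_len = math.ceil((EDGE_PAD + m + EDGE_PAD) / gran) * gran
    lo, hi = EDGE_PAD, EDGE_PAD + m - 1

    scaf = [[EMPTY_CELL] * array_len for _ in range(n)]
    stap = [[EMPTY_CELL] * array_len for _ in range(n)]

    # scaffold: horizontal serpentine raster; even helices run 5'->3' in
    # increasing idx, odd helices decreasing, crossing between neighbours
    # at the ends of the occupied region
    scaffold_path: list[tuple[int, int]] = []
    for h in range(n):
        idxs = range(lo, hi + 1) if h % 2 == 0 else range(hi, lo - 1, -1)
        scaffold_path.extend((h, i) for i in idxs)
    _set_links(scaf, scaffold_path)

    # staples: one unbroken vertical column serpentine per column; even
    # helices run in decreasing idx, odd increasing (antiparallel)
    stap_colors: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    c0 = lo
    for width in _column_widths(m, spec):
        c1 = c0 + width - 1
        path: list[tuple[int, int]] = []
        for h in range(n):
            idxs = range(c1, c0 - 1, -1) if h % 2 == 0 else range(c0, c1 + 1)
            path.extend((h, i) for i in idxs)
        _set_links(stap, path)
        h5, i5 = path[0]
        stap_colors[h5].append((i5, DEFAULT_COLOR))
        c0 = c1 + 1

    helices = [
        VirtualHelix(
            num=h,
            row=0,
            col=h,
            scaf=scaf[h],
            stap=stap[h],
            skip=[0] * array_len,
            loop=[0] * array_len,
            stap_colors=sorted(stap_colors[h]),
        )
        for h in range(n)
    ]
    name = f"bundle-{n}x{n * m}-{spec.lattice_kind}"
    return LatticeDesign(name=name, lattice_kind=spec.lattice_kind, helices=helices)


def duplex_toy() -> LatticeDesign:
    """The smallest fixture: 2 helices, 32 occupied cells each, one
    scaffold crossover and one unbroken 64-nt staple with one crossover."""
    return make_helix_bundle(2, 64)


def make_degenerate_cases() -> list[tuple[str, str]]:
    """Adversarial caDNAno files, each triggering a specific error.

    Returns ``(name, json_text)`` pairs:

    - ``empty_vstrands`` — schema error on parse
    - ``dangling_pointer`` — linkage error on parse
    - ``loop_insertion`` — unsupported-feature error on parse
    - ``two_scaffolds`` — parses, but scaffold tracing raises a topology
      error (two components)
    """
    toy = json.loads(write_design(duplex_toy()))
    cases: list[tuple[str, str]] = []

    cases.append(("empty_vstrands", json.dumps({"name": "degenerate", "vstrands": []})))

    dangling = json.loads(json.dumps(toy))
    # helix 0 scaffold 5' end now claims a successor in an empty cell
    dangling["vstrands"][0]["scaf"][EDGE_PAD][2:4] = [0, 0]
    cases.append(("dangling_pointer", json.dumps(dangling)))

    loopy = json.loads(json.dumps(toy))
    loopy["vstrands"][0]["loop"][EDGE_PAD + 4] = 1
    cases.append(("loop_insertion", json.dumps(loopy)))

    split = json.loads(json.dumps(toy))
    hi = EDGE_PAD + 31
    # sever the scaffold crossover consistently on both sides
    split["vstrands"][0]["scaf"][hi][2:4] = [-1, -1]
    split["vstrands"][1]["scaf"][hi][0:2] = [-1, -1]
    cases.append(("two_scaffolds", json.dumps(split)))
    return cases
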
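"""Read, validate and write caDNAno version-2 JSON design files.

caDNAno encodes an origami design as a list of "virtual helices"
(``vstrands``), each carrying two per-base linked lists — ``scaf`` and
``stap`` — whose entries are 4-tuples ``[prev_helix, prev_idx, next_helix,
next_idx]``. ``prev`` points toward the 5' end of the strand, ``next``
toward the 3' end, and ``-1`` is the sentinel for "no neighbour". A cell
with all four fields ``-1`` is unoccupied.

Only the version-2 dialect is supported (scadnano and caDNAno 2.5 files are
rejected with a clear message). ``skip`` values of ``-1`` are honoured —
the base is omitted from strand paths — while ``loop`` insertions (> 0) are
rejected as unsupported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

from .errors import (
    CadnanoParseError,
    LinkageError,
    SchemaError,
    UnsupportedFeatureError,
)

__all__ = [
    "BaseCell",
    "VirtualHelix",
    "LatticeDesign",
    "EMPTY_CELL",
    "parse_design",
    "write_design",
]


class BaseCell(NamedTuple):
    """One entry of a ``scaf``/``stap`` array: 5' and 3' neighbour pointers."""

    prev_helix: int
    prev_idx: int
    next_helix: int
    next_idx: int

    @property
    def is_empty(self) -> bool:
        return self == EMPTY_CELL

    @property
    def has_prev(self) -> bool:
        return self.prev_helix != -1

    @property
    def has_next(self) -> bool:
        return self.next_helix != -1


EMPTY_CELL = BaseCell(-1, -1, -1, -1)


@dataclass
class VirtualHelix:
    """One lattice helix: id, lattice coordinates and per-base linkage."""

    num: int
    row: int
    col: int
    scaf: list[BaseCell]
    stap: list[BaseCell]
    skip: list[int]
    loop: list[int]
    stap_colors: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.scaf)


@dataclass
class LatticeDesign:
    """In-memory model of a caDNAno version-2 file."""

    name: str
    lattice_kind: str  # "honeycomb" | "square"
    helices: list[VirtualHelix]

    @property
    def helix_by_num(self) -> dict[int, VirtualHelix]:
        return {h.num: h for h in self.helices}

    @property
    def array_length(self) -> int:
        return len(self.helices[0])

    def cells(self, kind: str) -> Iterator[tuple[int, int, BaseCell]]:
        """Yield ``(helix_num, idx, cell)`` for every occupied cell of a
        strand kind ("scaffold" or "staple"), excluding skipped bases."""
        attr = "scaf" if kind == "scaffold" else "stap"
        for helix in self.helices:
            arr = getattr(helix, attr)
            for idx, cell in enumerate(arr):
                if not cell.is_empty and helix.skip[idx] != -1:
                    yield helix.num, idx, cell


def _infer_lattice(array_length: int) -> str:
    # caDNAno pads arrays to multiples of 21 (honeycomb) or 32 (square).
    if array_length % 21 == 0:
        return "honeycomb"
    if array_length % 32 == 0:
        return "square"
    raise SchemaError(
        f"array length {array_length} is not a multiple of 21 (honeycomb) "
        "or 32 (square); not a caDNAno v2 design"
    )


def _as_cell(raw: object, helix: int, idx: int, kind: str) -> BaseCell:
    if (
        not isinstance(raw, list)
        or len(raw) != 4
        or not all(isinstance(v, int) and v >= -1 for v in raw)
    ):
        raise SchemaError(
            f"helix {helix} {kind}[{idx}]: expected 4 integers >= -1, got {raw!r}"
        )
    cell = BaseCell(*raw)
    if (cell.prev_helix == -1) != (cell.prev_idx == -1) or (
        cell.next_helix == -1
    ) != (cell.next_idx == -1):
        raise LinkageError(
            f"helix {helix} {kind}[{idx}]: half-sentinel pointer {raw!r}"
        )
    return cell


def parse_design(json_text: str) -> LatticeDesign:
    """Parse caDNAno v2 JSON text into a validated :class:`LatticeDesign`.

    Raises
    ------
    CadnanoParseError
        Malformed JSON.
    SchemaError
        Valid JSON that is not a caDNAno v2 design (including empty
        ``vstrands``).
    UnsupportedFeatureError
        scadnano / caDNAno 2.5 dialects, or loop insertions > 0.
    LinkageError
        A pointer dangles or pointer pairs are not mutually consistent.
    """
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise CadnanoParseError(f"malformed JSON: {exc}") from exc

    if not isinstance(doc, dict):
        raise SchemaError("top-level JSON value is not an object")
    if "grid" in doc or "helices" in doc:
        raise UnsupportedFeatureError(
            "this looks like a scadnano file; only caDNAno v2 is supported"
        )
    if "format" in doc:
        raise UnsupportedFeatureError(
            "this looks like a caDNAno 2.5 file; only caDNAno v2 is supported"
        )
    if "vstrands" not in doc:
        raise SchemaError('missing "vstrands" key')
    vstrands = doc["vstrands"]
    if not isinstance(vstrands, list) or not vstrands:
        raise SchemaError('"vstrands" must be a non-empty list')

    helices: list[VirtualHelix] = []
    for vs in vstrands:
        if not isinstance(vs, dict):
            raise SchemaError("vstrand entry is not an object")
        try:
            num = int(vs["num"])
            row = int(vs["row"])
            col = int(vs["col"])
            raw_scaf = vs["scaf"]
            raw_stap = vs["stap"]
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"vstrand missing required field: {exc}") from exc
        n = len(raw_scaf)
        if len(raw_stap) != n:
            raise SchemaError(f"helix {num}: scaf/stap length mismatch")
        skip = list(vs.get("skip", [0] * n))
        loop = list(vs.get("loop", [0] * n))
        if len(skip) != n or len(loop) != n:
            raise SchemaError(f"helix {num}: skip/loop length mismatch")
        if any(s not in (0, -1) for s in skip):
            raise SchemaError(f"helix {num}: skip values must be 0 or -1")
        if any(l < 0 for l in loop):
            raise SchemaError(f"helix {num}: loop values must be >= 0")
        if any(l > 0 for l in loop):
            raise UnsupportedFeatureError(
                f"helix {num} uses loop insertions, which are not supported"
            )
        scaf = [_as_cell(c, num, i, "scaf") for i, c in enumerate(raw_scaf)]
        stap = [_as_cell(c, num, i, "stap") for i, c in enumerate(raw_stap)]
        stap_colors = [
            (int(idx), int(color)) for idx, color in vs.get("stap_colors", [])
        ]
        helices.append(
            VirtualHelix(num, row, col, scaf, stap, skip, loop, stap_colors)
        )

    nums = [h.num for h in helices]
    if len(set(nums)) != len(nums):
        raise SchemaError(f"duplicate helix numbers: {sorted(nums)}")
    lengths = {len(h) for h in helices}
    if len(lengths) != 1:
        raise SchemaError(f"helices have differing array lengths: {sorted(lengths)}")

    design = LatticeDesign(
        name=str(doc.get("name", "")),
        lattice_kind=_infer_lattice(lengths.pop()),
        helices=helices,
    )
    _check_linkage(design)
    return design


def _check_linkage(design: LatticeDesign) -> None:
    """Every non-sentinel pointer must target an existing occupied cell and
    pointer pairs must be mutually consistent: A.next == B implies B.prev == A."""
    by_num = design.helix_by_num
    n = design.array_length
    for helix in design.helices:
        for kind, arr in (("scaf", helix.scaf), ("stap", helix.stap)):
            for idx, cell in enumerate(arr):
                if cell.is_empty:
                    continue
                for direction in ("next", "prev"):
                    th = getattr(cell, f"{direction}_helix")
                    ti = getattr(cell, f"{direction}_idx")
                    if th == -1:
                        continue
                    target_helix = by_num.get(th)
                    if target_helix is None or not (0 <= ti < n):
                        raise LinkageError(
                            f"helix {helix.num} {kind}[{idx}]: dangling "
                            f"{direction} pointer to ({th}, {ti})"
                        )
                    target = getattr(target_helix, kind)[ti]
                    back = "prev" if direction == "next" else "next"
                    if (
                        getattr(target, f"{back}_helix") != helix.num
                        or getattr(target, f"{back}_idx") != idx
                    ):
                        raise LinkageError(
                            f"helix {helix.num} {kind}[{idx}]: {direction} pointer "
                            f"to ({th}, {ti}) is not reciprocated"
                        )


def write_design(design: LatticeDesign) -> str:
    """Serialize a design back to caDNAno v2 JSON text.

    The output re-parses to an equal design, uses a stable field order, and
    is byte-identical across runs for equal inputs. The design is validated
    first, so an inconsistent design raises before anything is emitted.
    """
    _check_linkage(design)
    vstrands = []
    for helix in design.helices:
        if any(l > 0 for l in helix.loop):
            raise UnsupportedFeatureError(
                f"helix {helix.num} uses loop insertions, which are not supported"
            )
        vstrands.append(
            {
                "row": helix.row,
                "col": helix.col,
                "num": helix.num,
                "scaf": [list(c) for c in helix.scaf],
                "stap": [list(c) for c in helix.stap],
                "loop": list(helix.loop),
                "skip": list(helix.skip),
                "scafLoop": [],
                "stapLoop": [],
                "stap_colors": [list(sc) for sc in helix.stap_colors],
            }
        )
    return json.dumps({"name": design.name, "vstrands": vstrands})
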
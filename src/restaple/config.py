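"""Search configuration.

:class:`DesignConfig` collects every knob of the layout/sequence search:
the number of unique staple sequences ``k_unique``, the library size
``iterations``, staple length bounds (with the three named presets used for
the bundle geometries: ``short`` 25–62 nt, ``long`` 60–125 nt, ``bundle``
38–77 nt), the repeat window (minimum repeat length, default 12 nt), the
seed, optional predefined staple sequences, optional GC bounds, the
advisory forbidden-motif list (default: the BtsCI recognition site GGATG
and its reverse complement), and the balanced-multiplicity tolerance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["DesignConfig", "LENGTH_PRESETS"]

LENGTH_PRESETS: dict[str, tuple[int, int]] = {
    "short": (25, 62),
    "long": (60, 125),
    "bundle": (38, 77),
}

#: BtsCI recognition site and its reverse complement. Hits are advisory
#: (reported, never a hard failure): on the single-stranded scaffold BtsCI
#: cuts far less efficiently than on the double-stranded hairpin adapters.
DEFAULT_FORBIDDEN_MOTIFS: tuple[str, ...] = ("GGATG", "CATCC")


@dataclass(frozen=True)
class DesignConfig:
    k_unique: int
    iterations: int = 100
    n_best: int = 1
    len_min: int = 38
    len_max: int = 77
    window: int = 12
    seed: int = 0
    sequences: Optional[tuple[str, ...]] = None
    gc_min: Optional[float] = None
    gc_max: Optional[float] = None
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN_MOTIFS
    multiplicity_tol: int = 2
    palette_size: Optional[int] = None
    repetitive_arrangement: bool = False

    def __post_init__(self) -> None:
        if self.k_unique < 1:
            raise ValueError("k_unique must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (1 <= self.n_best <= self.iterations):
            raise ValueError("n_best must be in [1, iterations]")
        if self.len_min > self.len_max or self.len_min < 1:
            raise ValueError("need 1 <= len_min <= len_max")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.multiplicity_tol < 0:
            raise ValueError("multiplicity_tol must be >= 0")
        if (self.gc_min is None) != (self.gc_max is None):
            raise ValueError("gc_min and gc_max must be set together")
        if self.gc_min is not None and not (0 <= self.gc_min <= self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.palette_size is not None and self.palette_size < 1:
            raise ValueError("palette_size must be >= 1")
        if self.sequences is not None:
            object.__setattr__(
                self, "sequences", tuple(s.upper() for s in self.sequences)
            )
        object.__setattr__(
            self, "forbidden_motifs", tuple(m.upper() for m in self.forbidden_motifs)
        )

    @property
    def effective_palette_size(self) -> int:
        """Number of distinct staple lengths the segmenter may draw.

        Defaults to ceil(k_unique / 2), capped by the number of admissible
        lengths: using fewer distinct lengths than groups leaves room to
        split each length class into several near-equal groups, which keeps
        the balanced-multiplicity constraint satisfiable.
        """
        span = self.len_max - self.len_min + 1
        if self.palette_size is not None:
            return min(self.palette_size, span)
        return max(1, min((self.k_unique + 1) // 2, span))

    def replace(self, **kwargs) -> "DesignConfig":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sequences"] = list(self.sequences) if self.sequences else None
        d["forbidden_motifs"] = list(self.forbidden_motifs)
        return d

    @classmethod
    def with_preset(cls, preset: str, **kwargs) -> "DesignConfig":
        """Build a config from a named staple-length preset."""
        lo, hi = LENGTH_PRESETS[preset]
        return cls(len_min=lo, len_max=hi, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "DesignConfig":
        """Load a config from a YAML or JSON file; keyword overrides win."""
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        ) or {}
        preset = data.pop("preset", None)
        if preset is not None:
            data.setdefault("len_min", LENGTH_PRESETS[preset][0])
            data.setdefault("len_max", LENGTH_PRESETS[preset][1])
        for key in ("sequences", "forbidden_motifs"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        data.update(overrides)
        return cls(**data)
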
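"""Randomized design search: generate, score and rank candidate scaffolds.

Each draw builds a fresh staple layout, assigns sequences to its groups,
derives the forced-complementary scaffold, and scores its repeat coverage.
Draw ``i`` uses an independent random stream derived from
``(config.seed, i)``, so draws can be reordered without changing results
and the whole search is reproducible bit-for-bit. Candidates are ranked by
ascending coverage fraction, ties broken by draw index; infeasible draws
are recorded with their reasons and excluded from the ranking.
"""

from __future__ import annotations

import copy
import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cadnano import LatticeDesign, parse_design, write_design
from .config import DesignConfig
from .errors import ConsistencyError, LayoutInfeasibleError, SearchError
from .layout import StapleLayout, draw_layout
from .repeats import RepeatReport, repeat_coverage
from .sequences import (
    COMPLEMENT,
    ScaffoldSequence,
    SequenceSet,
    assign_sequences,
    derive_scaffold,
)
from .strands import (
    DesignMetrics,
    StrandPath,
    design_metrics,
    trace_scaffold,
    trace_staples,
)

__all__ = ["Candidate", "SearchResult", "run_search", "export_candidate", "export_result"]

logger = logging.getLogger(__name__)

# caDNAno staple colour palette, cycled per sequence group
GROUP_COLORS = (
    13369344, 16204552, 16225054, 11184640, 5749504, 29184,
    243362, 1507550, 7536862, 12060012, 3355443, 8947848,
)


@dataclass(frozen=True)
class Candidate:
    """One scored (layout, sequences, scaffold) triple."""

    index: int
    layout: StapleLayout
    sequences: SequenceSet
    scaffold: ScaffoldSequence
    report: RepeatReport
    metrics: DesignMetrics
    design: LatticeDesign = field(repr=False, compare=False, default=None)
    config: DesignConfig = field(repr=False, compare=False, default=None)

    @property
    def coverage(self) -> float:
        return self.report.coverage_fraction


@dataclass(frozen=True)
class SearchResult:
    """Ranked candidate library (ascending repeat coverage)."""

    ranked: tuple[Candidate, ...]
    failures: tuple[tuple[int, str], ...]
    config: DesignConfig
    seed: int

    @property
    def best(self) -> Candidate:
        return self.ranked[0]

    def ranking_frame(self) -> pd.DataFrame:
        """Library summary (rank, draw index, coverage) — the plot data."""
        return pd.DataFrame(
            {
                "rank": range(len(self.ranked)),
                "candidate_index": [c.index for c in self.ranked],
                "coverage_fraction": [c.coverage for c in self.ranked],
                "duplicated_windows": [
                    c.report.duplicated_window_count for c in self.ranked
                ],
                "staple_count": [c.metrics.staple_count for c in self.ranked],
            }
        )


def _draw_rng(seed: int, draw: int) -> random.Random:
    # string seeds hash via SHA-512 in CPython: stable across runs/platforms
    return random.Random(f"{seed}:{draw}")


def run_search(
    design: LatticeDesign,
    config: DesignConfig,
    progress: Optional[Callable[[int, Optional[float]], None]] = None,
) -> SearchResult:
    """Run ``config.iterations`` independent layout+sequence draws on a
    design with unbroken staple routing and rank them by repeat coverage."""
    scaffold_path = trace_scaffold(design)
    unbroken = trace_staples(design)

    candidates: list[Candidate] = []
    failures: list[tuple[int, str]] = []
    for i in range(config.iterations):
        rng = _draw_rng(config.seed, i)
        try:
            layout = draw_layout(unbroken, config, rng)
        except LayoutInfeasibleError as exc:
            failures.append((i, str(exc)))
            if progress:
                progress(i, None)
            continue
        seqs = assign_sequences(layout, config, rng)
        scaffold = derive_scaffold(scaffold_path, layout, seqs, rng)
        report = repeat_coverage(scaffold.bases, config.window)
        metrics = design_metrics(design, layout)
        candidates.append(
            Candidate(
                index=i,
                layout=layout,
                sequences=seqs,
                scaffold=scaffold,
                report=report,
                metrics=metrics,
                design=design,
                config=config,
            )
        )
        if progress:
            progress(i, report.coverage_fraction)

    if not candidates:
        raise SearchError(
            "all draws infeasible: "
            + "; ".join(f"draw {i}: {r}" for i, r in failures)
        )
    candidates.sort(key=lambda c: (c.coverage, c.index))
    return SearchResult(
        ranked=tuple(candidates),
        failures=tuple(failures),
        config=config,
        seed=config.seed,
    )


def _apply_breaks(design: LatticeDesign, layout: StapleLayout) -> LatticeDesign:
    """A copy of the design with staple breaks applied and one caDNAno
    colour per sequence group."""
    broken = copy.deepcopy(design)
    by_num = broken.helix_by_num
    for helix in broken.helices:
        helix.stap_colors = []
    for staple, gid in zip(layout.staples, layout.group_of):
        h5, i5 = staple.path.positions[0]
        h3, i3 = staple.path.positions[-1]
        first = by_num[h5].stap[i5]
        by_num[h5].stap[i5] = first._replace(prev_helix=-1, prev_idx=-1)
        last = by_num[h3].stap[i3]
        by_num[h3].stap[i3] = last._replace(next_helix=-1, next_idx=-1)
        by_num[h5].stap_colors.append((i5, GROUP_COLORS[gid % len(GROUP_COLORS)]))
    for helix in broken.helices:
        helix.stap_colors.sort()
    return broken


def _spans(path: StrandPath) -> str:
    return ";".join(f"{h}:{a}-{b}" for h, a, b in path.segments())


def _staple_table(candidate: Candidate) -> pd.DataFrame:
    layout = candidate.layout
    rows = []
    for idx, (staple, gid) in enumerate(zip(layout.staples, layout.group_of)):
        rows.append(
            {
                "staple_index": idx,
                "group_id": gid,
                "length": staple.length,
                "sequence": candidate.sequences[gid],
                "start": "%d:%d" % staple.path.positions[0],
                "binding_locations": _spans(staple.path),
            }
        )
    return pd.DataFrame(rows)


def export_candidate(candidate: Candidate, out_dir: str | Path) -> dict[str, Path]:
    """Write one candidate as a cross-validated file set.

    Emits ``cadnano.json`` (staple breaks applied, per-group colours),
    ``scaffold.fasta``, ``staples.fasta`` (one record per unique sequence,
    multiplicity in the header), ``staples.csv`` and ``report.json``. The
    exported files are then re-parsed and re-hybridized against each other;
    on any mismatch everything written is removed and
    :class:`ConsistencyError` is raised.
    """
    if candidate.design is None or candidate.config is None:
        raise ValueError("candidate lacks its design/config context")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    broken = _apply_breaks(candidate.design, candidate.layout)
    files = {
        "cadnano": out / "cadnano.json",
        "scaffold": out / "scaffold.fasta",
        "staples_fasta": out / "staples.fasta",
        "staples_csv": out / "staples.csv",
        "report": out / "report.json",
    }
    try:
        files["cadnano"].write_text(write_design(broken) + "\n")

        scaffold_rec = SeqRecord(
            Seq(candidate.scaffold.bases),
            id=f"{candidate.design.name}|candidate_{candidate.index}",
            description=f"repeat_coverage={candidate.coverage:.6f} "
            f"window={candidate.config.window}",
        )
        SeqIO.write([scaffold_rec], files["scaffold"], "fasta")

        group_sizes = {g: len(m) for g, m in candidate.layout.groups.items()}
        staple_recs = [
            SeqRecord(
                Seq(candidate.sequences[g]),
                id=f"group_{g}",
                description=f"multiplicity={group_sizes[g]} "
                f"length={len(candidate.sequences[g])}",
            )
            for g in range(candidate.layout.k)
        ]
        SeqIO.write(staple_recs, files["staples_fasta"], "fasta")

        _staple_table(candidate).to_csv(files["staples_csv"], index=False)

        report = {
            "candidate_index": candidate.index,
            "coverage_fraction": candidate.coverage,
            "duplicated_window_count": candidate.report.duplicated_window_count,
            "window": candidate.report.window,
            "unpaired_positions": list(candidate.scaffold.unpaired_positions),
            "metrics": candidate.metrics.as_dict(),
            "config": candidate.config.as_dict(),
            "seed": candidate.config.seed,
        }
        files["report"].write_text(json.dumps(report, indent=2) + "\n")

        _cross_validate(files, candidate)
    except ConsistencyError:
        for path in files.values():
            path.unlink(missing_ok=True)
        raise
    return files


def _cross_validate(files: dict[str, Path], candidate: Candidate) -> None:
    """Check the exported file set against itself (not in-memory objects):
    the JSON re-parses with the right staple count, and every staple base in
    the CSV is the Watson–Crick complement of the scaffold FASTA base at the
    same lattice cell."""
    design = parse_design(files["cadnano"].read_text())
    staple_paths = trace_staples(design)
    table = pd.read_csv(files["staples_csv"])
    if len(staple_paths) != len(table):
        raise ConsistencyError(
            f"exported JSON has {len(staple_paths)} staples, CSV has {len(table)}"
        )
    scaffold_rec = next(SeqIO.parse(str(files["scaffold"]), "fasta"))
    scaffold_seq = str(scaffold_rec.seq)
    scaffold_path = trace_scaffold(design)
    if len(scaffold_seq) != len(scaffold_path):
        raise ConsistencyError("scaffold FASTA length disagrees with traced path")
    cell_to_offset = {pos: o for o, pos in enumerate(scaffold_path.positions)}

    by_start = {row["start"]: row for _, row in table.iterrows()}
    groups_fasta = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(files["staples_fasta"]), "fasta")
    }
    for path in staple_paths:
        key = "%d:%d" % path.positions[0]
        if key not in by_start:
            raise ConsistencyError(f"no CSV row for staple starting at {key}")
        row = by_start[key]
        seq = row["sequence"]
        if groups_fasta.get(f"group_{row['group_id']}") != seq:
            raise ConsistencyError(f"CSV/FASTA sequence mismatch for {key}")
        if len(seq) != len(path):
            raise ConsistencyError(f"staple at {key}: length mismatch")
        for offset, cell in enumerate(path.positions):
            o = cell_to_offset.get(cell)
            if o is None:
                raise ConsistencyError(f"staple cell {cell} not on scaffold")
            if scaffold_seq[o] != COMPLEMENT[seq[offset]]:
                raise ConsistencyError(
                    f"non-complementary pairing at cell {cell}"
                )


def export_result(result: SearchResult, out_dir: str | Path) -> dict:
    """Export the top ``n_best`` candidates plus the library summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exported = []
    for rank, candidate in enumerate(result.ranked[: result.config.n_best]):
        sub = out / f"candidate_{rank:03d}"
        export_candidate(candidate, sub)
        exported.append(
            {
                "rank": rank,
                "candidate_index": candidate.index,
                "coverage_fraction": candidate.coverage,
                "directory": sub.name,
            }
        )
    result.ranking_frame().to_csv(out / "ranking.csv", index=False)
    summary = {
        "seed": result.seed,
        "iterations": result.config.iterations,
        "feasible": len(result.ranked),
        "infeasible": len(result.failures),
        "failures": [{"draw": i, "reason": r} for i, r in result.failures],
        "config": result.config.as_dict(),
        "exported": exported,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
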
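"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: repeat coverage is
recomputed by brute-force all-pairs window comparison on integer-encoded
windows, and Watson-Crick pairing is re-checked by walking every lattice
cell from scratch.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

WC = {"A": "T", "T": "A", "C": "G", "G": "C"}

_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def naive_repeat_mask(seq: str, window: int) -> tuple[np.ndarray, int]:
    """All-pairs window-comparison oracle.

    Encodes every window as an integer and compares all pairs explicitly;
    returns (covered mask, number of duplicated window starts).
    """
    seq = seq.upper()
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    k = n - window + 1
    if k < 2:
        return mask, 0
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    assert codes.min() >= 0, "non-ACGT input"
    weights = 4 ** np.arange(window, dtype=np.int64)
    win = sliding_window_view(codes, window) @ weights
    eq = win[:, None] == win[None, :]
    np.fill_diagonal(eq, False)
    dup = eq.any(axis=1)
    for i in np.nonzero(dup)[0]:
        mask[i : i + window] = True
    return mask, int(dup.sum())


def wc_mismatches(scaffold_path, scaffold_bases, layout, seqs):
    """Re-hybridize every staple against the scaffold, cell by cell.

    Returns (paired cell count, mismatch count). Independent of
    derive_scaffold: builds its own cell->offset map from the scaffold path
    and reads staple bases directly from the group sequences.
    """
    offset_of = {pos: o for o, pos in enumerate(scaffold_path.positions)}
    paired = 0
    mismatches = 0
    for staple, gid in zip(layout.staples, layout.group_of):
        seq = seqs[gid]
        for j, cell in enumerate(staple.path.positions):
            paired += 1
            o = offset_of[cell]
            if scaffold_bases[o] != WC[seq[j]]:
                mismatches += 1
    return paired, mismatches


def check_exported_candidate(out_dir: Path):
    """Validate an exported candidate from its files alone.

    Re-parses the caDNAno JSON, traces strands, and checks every staple
    base in the CSV table against the scaffold FASTA. Returns a dict with
    pairing statistics and the number of distinct staple sequences.
    """
    from Bio import SeqIO

    from restaple import parse_design, trace_scaffold, trace_staples

    out_dir = Path(out_dir)
    design = parse_design((out_dir / "cadnano.json").read_text())
    scaffold_path = trace_scaffold(design)
    staple_paths = trace_staples(design)
    scaffold = str(next(SeqIO.parse(str(out_dir / "scaffold.fasta"), "fasta")).seq)
    table = pd.read_csv(out_dir / "staples.csv")
    report = json.loads((out_dir / "report.json").read_text())

    offset_of = {pos: o for o, pos in enumerate(scaffold_path.positions)}
    rows = {row["start"]: row for _, row in table.iterrows()}
    paired = mismatches = 0
    for path in staple_paths:
        row = rows["%d:%d" % path.positions[0]]
        seq = row["sequence"]
        assert len(seq) == len(path)
        for j, cell in enumerate(path.positions):
            paired += 1
            if scaffold[offset_of[cell]] != WC[seq[j]]:
                mismatches += 1
    return {
        "paired": paired,
        "mismatches": mismatches,
        "staple_count": len(staple_paths),
        "distinct_sequences": table["sequence"].nunique(),
        "scaffold_length": len(scaffold),
        "report": report,
    }


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
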
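import json
import random

import pytest
from Bio.Seq import Seq

from restaple import (
    DesignConfig,
    assign_sequences,
    count_motif,
    derive_scaffold,
    draw_layout,
    flank_with_adapters,
    parse_design,
    random_sequence,
    trace_scaffold,
    trace_staples,
)
from restaple.errors import SequenceAssignmentError
from restaple.layout import Staple, StapleLayout
from restaple.sequences import COMPLEMENT, ScaffoldSequence, SequenceSet

from .oracles import wc_mismatches

CFG = DesignConfig(k_unique=1)


class TestRandomSequence:
    def test_deterministic_per_seed(self):
        a = random_sequence(12, CFG, random.Random(5))
        b = random_sequence(12, CFG, random.Random(5))
        assert a == b
        assert len(a) == 12 and set(a) <= set("ACGT")

    def test_gc_bounds_are_enforced(self):
        config = CFG.replace(gc_min=0.4, gc_max=0.6)
        for seed in range(20):
            seq = random_sequence(10, config, random.Random(seed))
            assert seq.count("G") + seq.count("C") in (4, 5, 6)

    def test_zero_length_is_an_argument_error(self):
        with pytest.raises(ValueError):
            random_sequence(0, CFG, random.Random(0))


def _toy_layout_and_scaffold(toy, k, rng_seed=0, len_bounds=(32, 32)):
    unbroken = trace_staples(toy)
    config = DesignConfig(k_unique=k, len_min=len_bounds[0], len_max=len_bounds[1])
    layout = draw_layout(unbroken, config, random.Random(rng_seed))
    return trace_scaffold(toy), layout, config


class TestAssignSequences:
    def test_predefined_sequences_used_verbatim(self, toy):
        _, layout, config = _toy_layout_and_scaffold(toy, k=2)
        provided = ("A" * 32, "C" * 32)
        seqs = assign_sequences(
            layout, config.replace(sequences=provided), random.Random(0)
        )
        assert seqs.provenance == "predefined"
        assert sorted(seqs.sequences) == sorted(provided)

    def test_wrong_length_predefined_entry_is_an_error(self, toy):
        _, layout, config = _toy_layout_and_scaffold(toy, k=2)
        with pytest.raises(SequenceAssignmentError, match="length"):
            assign_sequences(
                layout,
                config.replace(sequences=("A" * 32, "C" * 31)),
                random.Random(0),
            )

    def test_wrong_count_is_an_error(self, toy):
        _, layout, config = _toy_layout_and_scaffold(toy, k=2)
        with pytest.raises(SequenceAssignmentError):
            assign_sequences(
                layout, config.replace(sequences=("A" * 32,)), random.Random(0)
            )

    def test_random_mode_yields_k_distinct_sequences(self, bundle24):
        unbroken = trace_staples(bundle24)
        config = DesignConfig(k_unique=5)
        layout = draw_layout(unbroken, config, random.Random(1))
        seqs = assign_sequences(layout, config, random.Random(1))
        assert seqs.provenance == "random"
        assert len(set(seqs.sequences)) == 5


class TestDeriveScaffold:
    def test_single_helix_duplex_is_a_reverse_complement(self):
        # one 12-nt helix: scaffold 5'->3' left-to-right, staple right-to-left
        array_len = 32
        scaf = [[-1, -1, -1, -1] for _ in range(array_len)]
        stap = [[-1, -1, -1, -1] for _ in range(array_len)]
        for i in range(12):
            scaf[i] = ([0, i - 1] if i else [-1, -1]) + (
                [0, i + 1] if i < 11 else [-1, -1]
            )
            stap[i] = ([0, i + 1] if i < 11 else [-1, -1]) + (
                [0, i - 1] if i else [-1, -1]
            )
        design = parse_design(
            json.dumps(
                {
                    "name": "duplex",
                    "vstrands": [
                        {
                            "row": 0,
                            "col": 0,
                            "num": 0,
                            "scaf": scaf,
                            "stap": stap,
                            "loop": [0] * array_len,
                            "skip": [0] * array_len,
                            "stap_colors": [],
                        }
                    ],
                }
            )
        )
        staple_path = trace_staples(design)[0]
        layout = StapleLayout(
            staples=(Staple.from_path(staple_path),), group_of=(0,), k=1
        )
        seqs = SequenceSet(sequences=("ACGTTGCAGGTT",), provenance="predefined")
        scaffold = derive_scaffold(
            trace_scaffold(design), layout, seqs, random.Random(0)
        )
        assert scaffold.bases == str(Seq("ACGTTGCAGGTT").reverse_complement())
        assert scaffold.unpaired_positions == ()

    def test_full_toy_pairing_passes_the_rehybridization_oracle(self, toy):
        scaffold_path, layout, config = _toy_layout_and_scaffold(toy, k=2)
        seqs = assign_sequences(layout, config, random.Random(7))
        scaffold = derive_scaffold(scaffold_path, layout, seqs, random.Random(7))
        paired, mismatches = wc_mismatches(
            scaffold_path, scaffold.bases, layout, seqs
        )
        assert paired == 64
        assert mismatches == 0

    def test_uncovered_positions_are_filled_and_recorded(self, toy):
        scaffold_path, layout, config = _toy_layout_and_scaffold(toy, k=2)
        partial = StapleLayout(
            staples=layout.staples[:1], group_of=(0,), k=1
        )
        seqs = SequenceSet(sequences=("A" * 32,), provenance="predefined")
        a = derive_scaffold(scaffold_path, partial, seqs, random.Random(3))
        b = derive_scaffold(scaffold_path, partial, seqs, random.Random(3))
        assert len(a.unpaired_positions) == 32
        assert a.bases == b.bases  # deterministic fill

    def test_determinism_end_to_end(self, toy):
        scaffold_path, layout, config = _toy_layout_and_scaffold(toy, k=2)
        seq_a = derive_scaffold(
            scaffold_path, layout, assign_sequences(layout, config, random.Random(9)),
            random.Random(9),
        )
        seq_b = derive_scaffold(
            scaffold_path, layout, assign_sequences(layout, config, random.Random(9)),
            random.Random(9),
        )
        assert seq_a.bases == seq_b.bases


class TestMotifs:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [
            ("GGATGGGATG", "GGATG", 2),
            ("AAAAAA", "AAAA", 3),
            ("", "GGATG", 0),
            ("ACGT", "acgt", 1),
        ],
    )
    def test_overlapping_motif_counts(self, seq, motif, expected):
        assert count_motif(seq, motif) == expected

    def test_empty_motif_is_an_error(self):
        with pytest.raises(ValueError):
            count_motif("ACGT", "")


class TestAdapters:
    def test_flanking_adds_both_adapters(self):
        out = flank_with_adapters(ScaffoldSequence(bases="ACGT" * 10), "A" * 30, "G" * 30)
        assert len(out) == 100
        assert out.startswith("A" * 30) and out.endswith("G" * 30)

    def test_empty_adapters_are_the_identity(self):
        out = flank_with_adapters("ACGTACGT", "", "")
        assert out == "ACGTACGT"

    def test_forbidden_motif_hits_are_warned(self, caplog):
        with caplog.at_level("WARNING", logger="restaple.sequences"):
            flank_with_adapters(
                "AAGGATGAA", "", "", forbidden_motifs=("GGATG", "CATCC")
            )
        assert any("forbidden-motif" in r.message for r in caplog.records)

    def test_non_acgt_adapter_is_an_error(self):
        with pytest.raises(ValueError):
            flank_with_adapters("ACGT", "ANN", "")
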
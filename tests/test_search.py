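import dataclasses
import json
from pathlib import Path

import pytest

from restaple import (
    DesignConfig,
    export_candidate,
    export_result,
    parse_design,
    repeat_coverage,
    run_search,
    trace_staples,
)
from restaple.errors import ConsistencyError, SearchError
from restaple.sequences import ScaffoldSequence

from .oracles import check_exported_candidate


@pytest.fixture(scope="module")
def small_search(bundle24):
    config = DesignConfig(k_unique=10, iterations=5, seed=7)
    return run_search(bundle24, config)


class TestRunSearch:
    def test_ranking_is_sorted_ascending(self, small_search):
        covs = [c.coverage for c in small_search.ranked]
        assert covs == sorted(covs)
        assert len(small_search.ranked) + len(small_search.failures) == 5

    def test_same_seed_reproduces_scores(self, bundle24, small_search):
        again = run_search(bundle24, DesignConfig(k_unique=10, iterations=5, seed=7))
        assert [c.coverage for c in again.ranked] == [
            c.coverage for c in small_search.ranked
        ]
        assert [c.scaffold.bases for c in again.ranked] == [
            c.scaffold.bases for c in small_search.ranked
        ]

    def test_rescoring_exported_scaffolds_reproduces_the_ranking(self, small_search):
        rescored = [
            repeat_coverage(c.scaffold.bases, small_search.config.window).coverage_fraction
            for c in small_search.ranked
        ]
        assert rescored == [c.coverage for c in small_search.ranked]
        assert rescored == sorted(rescored)

    def test_all_draws_infeasible_raises_search_error(self, toy):
        # the toy's 64-nt staple path cannot be cut into staples of 70-77 nt
        with pytest.raises(SearchError):
            run_search(toy, DesignConfig(k_unique=2, iterations=3, len_min=70, len_max=77))

    def test_sequence_reuse_is_exact(self, small_search):
        for candidate in small_search.ranked:
            distinct = {
                candidate.sequences[g] for g in range(candidate.layout.k)
            }
            assert len(distinct) == candidate.config.k_unique


class TestExport:
    def test_exported_file_set_is_internally_consistent(self, small_search, tmp_path):
        candidate = small_search.best
        files = export_candidate(candidate, tmp_path / "best")
        assert all(p.exists() for p in files.values())

        checked = check_exported_candidate(tmp_path / "best")
        assert checked["mismatches"] == 0
        assert checked["staple_count"] == candidate.metrics.staple_count
        assert checked["distinct_sequences"] == candidate.config.k_unique
        assert checked["scaffold_length"] == candidate.metrics.scaffold_length

        # breaks applied: the JSON now traces one staple per layout staple
        design = parse_design((tmp_path / "best" / "cadnano.json").read_text())
        assert len(trace_staples(design)) == len(candidate.layout.staples)
        # per-group colours present on 5' helices
        colors = [c for h in design.helices for c in h.stap_colors]
        assert len(colors) == len(candidate.layout.staples)

    def test_staple_fasta_has_one_record_per_group(self, small_search, tmp_path):
        from Bio import SeqIO

        export_candidate(small_search.best, tmp_path / "x")
        records = list(SeqIO.parse(str(tmp_path / "x" / "staples.fasta"), "fasta"))
        assert len(records) == small_search.config.k_unique
        assert all("multiplicity=" in r.description for r in records)

    def test_exports_are_byte_identical_across_runs(self, bundle24, tmp_path):
        config = DesignConfig(k_unique=10, iterations=3, seed=11, n_best=2)
        for d in ("a", "b"):
            export_result(run_search(bundle24, config), tmp_path / d)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [p.name for p in files_a] == [p.name for p in files_b]
        for pa, pb in zip(files_a, files_b):
            if pa.is_file():
                assert pa.read_bytes() == pb.read_bytes(), pa.name

    def test_tampered_candidate_fails_cross_validation_and_keeps_nothing(
        self, small_search, tmp_path
    ):
        candidate = small_search.best
        bases = candidate.scaffold.bases
        flipped = {"A": "C", "C": "A", "G": "T", "T": "G"}[bases[5]]
        tampered = dataclasses.replace(
            candidate,
            scaffold=ScaffoldSequence(
                bases=bases[:5] + flipped + bases[6:],
                unpaired_positions=candidate.scaffold.unpaired_positions,
            ),
        )
        out = tmp_path / "tampered"
        with pytest.raises(ConsistencyError):
            export_candidate(tampered, out)
        assert not any(out.glob("*"))

    def test_summary_and_ranking_match_the_result(self, small_search, tmp_path):
        summary = export_result(small_search, tmp_path / "out")
        assert summary["feasible"] == len(small_search.ranked)
        ranking = (tmp_path / "out" / "ranking.csv").read_text().splitlines()
        assert len(ranking) == 1 + len(small_search.ranked)
        report = json.loads(
            (tmp_path / "out" / "candidate_000" / "report.json").read_text()
        )
        assert report["coverage_fraction"] == pytest.approx(
            small_search.best.coverage
        )
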
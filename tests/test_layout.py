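import random
from itertools import combinations

import pytest

from restaple import (
    DesignConfig,
    assign_groups,
    draw_layout,
    make_helix_bundle,
    segment_paths,
    trace_staples,
    validate_layout,
)
from restaple.errors import LayoutInfeasibleError
from restaple.layout import Staple
from restaple.strands import StrandPath


def _path(length, helix=0):
    return StrandPath(kind="staple", positions=tuple((helix, i) for i in range(length)))


def _staple(length, helix=0):
    return Staple.from_path(_path(length, helix))


CFG = DesignConfig(k_unique=2, len_min=38, len_max=77)


class TestSegmentPaths:
    def test_forced_single_length_palette(self):
        staples = segment_paths([_path(120)], CFG.replace(len_min=60, len_max=60),
                                random.Random(0), palette=[60])
        assert [s.length for s in staples] == [60, 60]

    def test_two_length_palette_partitions_exactly(self):
        staples = segment_paths([_path(130)], CFG, random.Random(0), palette=[60, 70])
        assert sorted(s.length for s in staples) == [60, 70]

    def test_path_shorter_than_len_min_is_infeasible(self):
        with pytest.raises(LayoutInfeasibleError, match="len_min"):
            segment_paths([_path(30)], CFG, random.Random(0))

    def test_unpartitionable_length_exhausts_palette_budget(self):
        # a 41-nt path cannot be tiled by any subset of lengths in [38, 77]
        # other than {41}; force a palette without it
        with pytest.raises(LayoutInfeasibleError):
            segment_paths([_path(41)], CFG, random.Random(0), palette=[40])


class TestAssignGroups:
    def test_uniform_lengths_split_evenly(self):
        staples = [_staple(60, h) for h in range(100)]
        layout = assign_groups(staples, DesignConfig(k_unique=10), random.Random(1))
        sizes = sorted(len(m) for m in layout.groups.values())
        assert sizes == [10] * 10

    def test_two_length_classes_map_to_two_groups(self):
        staples = [_staple(60, h) for h in range(50)] + [
            _staple(70, h) for h in range(50, 100)
        ]
        layout = assign_groups(staples, DesignConfig(k_unique=2), random.Random(1))
        assert sorted(len(m) for m in layout.groups.values()) == [50, 50]
        for members in layout.groups.values():
            assert len({layout.staples[i].length for i in members}) == 1

    def test_fewer_staples_than_groups_is_infeasible(self):
        with pytest.raises(LayoutInfeasibleError):
            assign_groups([_staple(60)] * 5, DesignConfig(k_unique=10), random.Random(0))


class TestValidateLayout:
    def test_mixed_length_group_is_reported(self):
        from restaple.layout import StapleLayout

        layout = StapleLayout(
            staples=(_staple(60), _staple(61)), group_of=(0, 0), k=1
        )
        violations = validate_layout(layout, DesignConfig(k_unique=1))
        assert any("mixes staple lengths" in v for v in violations)

    def test_out_of_bounds_staple_is_reported(self):
        from restaple.layout import StapleLayout

        layout = StapleLayout(staples=(_staple(30),), group_of=(0,), k=1)
        violations = validate_layout(layout, DesignConfig(k_unique=1))
        assert any("outside [38, 77]" in v for v in violations)


class TestDrawLayout:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generated_layouts_have_no_violations(self, bundle24, seed):
        unbroken = trace_staples(bundle24)
        config = DesignConfig(k_unique=10, seed=seed)
        layout = draw_layout(unbroken, config, random.Random(seed))
        assert validate_layout(layout, config) == []
        # partition exactness: concatenated staples reproduce each path
        flat = [pos for s in layout.staples for pos in s.path.positions]
        source = [pos for p in unbroken for pos in p.positions]
        assert flat == source
        # balanced multiplicities
        target = layout.staple_count / layout.k
        assert all(
            abs(len(m) - target) <= config.multiplicity_tol
            for m in layout.groups.values()
        )

    def test_same_seed_reproduces_the_layout(self, bundle24):
        unbroken = trace_staples(bundle24)
        config = DesignConfig(k_unique=15)
        a = draw_layout(unbroken, config, random.Random(42))
        b = draw_layout(unbroken, config, random.Random(42))
        assert a.group_of == b.group_of
        assert [s.length for s in a.staples] == [s.length for s in b.staples]


def _same_signature_fraction(layout):
    pairs = same = 0
    for members in layout.groups.values():
        for i, j in combinations(members, 2):
            pairs += 1
            same += layout.staples[i].signature == layout.staples[j].signature
    return same / pairs if pairs else 0.0


class TestArrangementDiversity:
    def test_random_breaks_diversify_crossover_signatures(self, bundle24):
        unbroken = trace_staples(bundle24)
        layout = draw_layout(unbroken, DesignConfig(k_unique=10), random.Random(3))
        assert _same_signature_fraction(layout) < 1.0

    def test_repetitive_mode_forces_identical_signatures(self):
        design = make_helix_bundle(6, 1092, "honeycomb", 7)
        unbroken = trace_staples(design)
        config = DesignConfig(
            k_unique=2, repetitive_arrangement=True, multiplicity_tol=6
        )
        layout = draw_layout(unbroken, config, random.Random(0))
        assert _same_signature_fraction(layout) == 1.0
        assert validate_layout(layout, config) == []
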
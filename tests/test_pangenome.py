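from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chunkcall.errors import UnknownContigError, ValidationError
from chunkcall.fixtures import synth_presence_maps
from chunkcall.genome_index import GenomeIndex
from chunkcall.pangenome import (
    GeneGroupMembership,
    LabeledInterval,
    PresenceMap,
    absent_gene_groups,
    absent_regions,
    classify_gene_groups,
    classify_regions,
    count_snps_by_class,
    read_presence_bed,
    write_classified_bed,
)

FRAME = GenomeIndex((("chr", 100),))


def _pm(genome_id, *intervals, chrom="chr"):
    return PresenceMap(genome_id, tuple((chrom, s, e) for s, e in intervals))


def _per_base_oracle(maps, frame):
    """Brute-force per-base occupancy labels."""
    labels = {}
    for chrom, length in frame:
        arr = np.zeros(length + 1, dtype=int)
        for pm in maps:
            for c, s, e in pm.intervals:
                if c == chrom:
                    arr[s : e + 1] += 1
        n = len(maps)
        for pos in range(1, length + 1):
            c = arr[pos]
            if c == 0:
                continue
            labels[(chrom, pos)] = (
                "core" if c == n else ("specific" if c == 1 else "dispensable"), c
            )
    return labels


def _flatten(labeled):
    out = {}
    for li in labeled:
        for pos in range(li.start, li.end + 1):
            out[(li.chrom, pos)] = (li.label, li.occupancy)
    return out


class TestClassifyRegions:
    def test_full_triple_coverage_is_one_core_interval(self):
        maps = [_pm(g, (1, 100)) for g in "ABC"]
        assert classify_regions(maps, FRAME) == [
            LabeledInterval("chr", 1, 100, "core", 3)
        ]

    def test_staggered_coverage_splits_specific_and_core(self):
        maps = [_pm("A", (1, 10)), _pm("B", (5, 10)), _pm("C", (5, 10))]
        assert classify_regions(maps, FRAME) == [
            LabeledInterval("chr", 1, 4, "specific", 1),
            LabeledInterval("chr", 5, 10, "core", 3),
        ]

    def test_all_maps_empty_gives_no_labels(self):
        assert classify_regions([_pm("A"), _pm("B")], FRAME) == []

    def test_needs_two_genomes(self):
        with pytest.raises(ValidationError):
            classify_regions([_pm("A", (1, 5))], FRAME)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(UnknownContigError):
            classify_regions(
                [_pm("A", (1, 5), chrom="nope"), _pm("B", (1, 5))], FRAME
            )

    def test_interval_past_chromosome_end_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            classify_regions([_pm("A", (90, 120)), _pm("B", (1, 5))], FRAME)

    def test_labels_invariant_under_map_order(self):
        maps = [_pm("A", (1, 30), (60, 80)), _pm("B", (20, 70)), _pm("C", (25, 26))]
        forward = classify_regions(maps, FRAME)
        assert classify_regions(maps[::-1], FRAME) == forward

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_agrees_with_per_base_occupancy_oracle(self, data):
        frame = GenomeIndex((("c1", 120), ("c2", 80)))
        n_genomes = data.draw(st.integers(2, 5))
        maps = []
        for g in range(n_genomes):
            intervals = []
            for chrom, length in frame:
                cursor = 1
                while cursor <= length:
                    start = data.draw(st.integers(cursor, length + 30))
                    if start > length:
                        break
                    end = data.draw(st.integers(start, min(start + 40, length)))
                    intervals.append((chrom, start, end))
                    cursor = end + 2  # keep intervals disjoint, gap >= 1
            maps.append(PresenceMap(f"G{g}", tuple(intervals)))
        labeled = classify_regions(maps, frame)
        assert _flatten(labeled) == _per_base_oracle(maps, frame)

    def test_base_count_conservation(self):
        """Sum of occupancy x span over fragments == total covered bases."""
        maps = [_pm("A", (1, 50)), _pm("B", (20, 90)), _pm("C", (40, 60))]
        labeled = classify_regions(maps, FRAME)
        assert sum(li.occupancy * li.span for li in labeled) == sum(
            pm.covered_bases() for pm in maps
        )


class TestAbsentRegions:
    MAPS = [_pm("A", (1, 50)), _pm("B", (30, 80)), _pm("C", (1, 20))]

    def test_focal_covering_everything_yields_nothing(self):
        maps = [_pm("A", (1, 100)), _pm("B", (10, 20))]
        assert absent_regions(maps, FRAME, "A") == []

    def test_empty_focal_returns_other_coverage(self):
        maps = [_pm("A"), _pm("B", (1, 50))]
        assert absent_regions(maps, FRAME, "A") == [("chr", 1, 50)]

    def test_staggered_matches_per_base_reasoning(self):
        # A covers 1-50; B covers 30-80, C covers 1-20 -> absent from A: 51-80
        assert absent_regions(self.MAPS, FRAME, "A") == [("chr", 51, 80)]
        # absent from C: 21-80 (A and/or B cover it)
        assert absent_regions(self.MAPS, FRAME, "C") == [("chr", 21, 80)]

    def test_unknown_focal_rejected(self):
        with pytest.raises(ValidationError, match="focal"):
            absent_regions(self.MAPS, FRAME, "Z")


class TestGeneGroups:
    PANEL = [f"G{i}" for i in range(16)]

    def test_occupancy_rules(self):
        groups = [
            GeneGroupMembership("core1", frozenset(self.PANEL)),
            GeneGroupMembership("priv1", frozenset(["G3"])),
            GeneGroupMembership("disp1", frozenset(self.PANEL[:7])),
        ]
        assert classify_gene_groups(groups, self.PANEL) == {
            "core1": "core", "priv1": "private", "disp1": "dispensable"
        }

    def test_focal_absent_groups(self):
        almost = GeneGroupMembership("g15", frozenset(self.PANEL[1:]))  # all but G0
        other = GeneGroupMembership("g14", frozenset(self.PANEL[2:]))  # 14 members
        assert absent_gene_groups([almost, other], self.PANEL, "G0") == ["g15"]
        assert absent_gene_groups([almost, other], self.PANEL, "G5") == []

    def test_member_outside_panel_rejected(self):
        bad = GeneGroupMembership("x", frozenset(["G0", "alien"]))
        with pytest.raises(ValidationError, match="outside the panel"):
            classify_gene_groups([bad], self.PANEL)

    def test_empty_membership_rejected(self):
        with pytest.raises(ValidationError):
            GeneGroupMembership("x", frozenset())


class TestCountSnpsByClass:
    LABELED = [
        LabeledInterval("chr", 1, 40, "core", 3),
        LabeledInterval("chr", 41, 60, "dispensable", 2),
        LabeledInterval("chr", 61, 70, "specific", 1),
    ]

    def test_counts_inside_fragments(self):
        variants = [("chr", p) for p in (1, 5, 40, 41, 60, 61, 70, 99)]
        assert count_snps_by_class(variants, self.LABELED) == Counter(
            core=3, dispensable=2, specific=2, unclassified=1
        )

    def test_boundary_position_belongs_to_its_inclusive_fragment(self):
        assert count_snps_by_class([("chr", 40)], self.LABELED) == Counter(core=1)
        assert count_snps_by_class([("chr", 41)], self.LABELED) == Counter(
            dispensable=1
        )

    def test_planted_panel_recovers_exact_counts(self, small_frame, cohort):
        fixture = synth_presence_maps(11, small_frame, 5)
        labeled = classify_regions(fixture.maps, small_frame)
        variants = list(zip(cohort.truth.chrom, cohort.truth.pos))
        counts = count_snps_by_class(variants, labeled)
        # oracle: per-variant containment scan over the planted truth intervals
        expected = Counter()
        for chrom, pos in variants:
            for li in fixture.truth_intervals:
                if li.chrom == chrom and li.start <= pos <= li.end:
                    expected[li.label] += 1
                    break
            else:
                expected["unclassified"] += 1
        assert counts == expected
        assert sum(counts.values()) == len(variants)


class TestBedIo:
    def test_bed_half_open_to_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "p.bed"
        bed.write_text("chr\t4\t5\nchr\t10\t20\n")
        pm = read_presence_bed(bed, "G1")
        assert pm.intervals == (("chr", 5, 5), ("chr", 11, 20))

    def test_classified_bed_round_trip(self, tmp_path):
        labeled = [LabeledInterval("chr", 5, 10, "core", 4)]
        out = tmp_path / "out.bed"
        write_classified_bed(labeled, out)
        assert out.read_text() == "chr\t4\t10\tcore\t4\n"

    def test_overlapping_presence_intervals_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            PresenceMap("G1", (("chr", 1, 10), ("chr", 5, 20)))
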
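import pytest

from rpa.loci import (consensus_block_coordinates, harmonize_block_groups,
                      select_common_loci)

from conftest import make_group, make_read


def two_sample_locus(spec_a, spec_b):
    ga = make_group(spec_a, sample="A")
    gb = make_group(spec_b, sample="B")
    (locus,) = select_common_loci({"A": [ga], "B": [gb]})
    return locus


class TestSelectCommonLoci:
    def test_region_absent_in_one_sample_excluded(self):
        ga = make_group([[(100, 22, 30)]], sample="A")
        gb = make_group([[(5000, 22, 30)]], sample="B")
        assert select_common_loci({"A": [ga], "B": [gb]}) == []

    def test_present_in_all_samples_included(self):
        locus = two_sample_locus([[(100, 22, 30)]], [[(101, 22, 25)]])
        assert set(locus.groups) == {"A", "B"}

    def test_one_nucleotide_overlap_suffices(self):
        # A spans 100-122, B spans 121-143: 1-nt overlap -> one locus
        locus = two_sample_locus([[(100, 22, 30)]], [[(121, 22, 30)]])
        assert locus.start == 100 and locus.end == 143

    def test_zero_overlap_is_not_a_locus(self):
        ga = make_group([[(100, 22, 30)]], sample="A")
        gb = make_group([[(122, 22, 30)]], sample="B")  # adjacent, no overlap
        assert select_common_loci({"A": [ga], "B": [gb]}) == []


class TestConsensusCoordinates:
    def test_high_reciprocal_overlap_merges(self):
        locus = two_sample_locus([[(100, 20, 30)]], [[(101, 20, 25)]])
        assert consensus_block_coordinates(locus) == [(100, 120)]  # 19/20 = 95%

    def test_low_overlap_stays_separate(self):
        locus = two_sample_locus([[(100, 20, 30)]], [[(112, 20, 25)]])
        assert len(consensus_block_coordinates(locus)) == 2  # 8/20 = 40%

    def test_identical_blocks_yield_distinct_count(self):
        locus = two_sample_locus(
            [[(100, 22, 30)], [(150, 22, 10)]],
            [[(100, 22, 28)], [(150, 22, 12)]],
        )
        assert consensus_block_coordinates(locus) == [(100, 122), (150, 172)]

    def test_residual_pairs_overlap_below_threshold(self):
        locus = two_sample_locus(
            [[(100, 20, 30)], [(150, 20, 10)]],
            [[(103, 20, 28)], [(155, 20, 12)]],
        )
        coords = consensus_block_coordinates(locus)
        from rpa.loci import _reciprocal_overlap

        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                assert _reciprocal_overlap(coords[i], coords[j]) < 0.90


class TestHarmonize:
    def reads(self, sample, specs):
        return [make_read(s, ln, c, sample=sample) for s, ln, c in specs]

    def test_empty_coordinate_gets_dummy_only_block(self):
        # B has no reads in the second consensus block
        locus = two_sample_locus(
            [[(100, 22, 30)], [(150, 22, 10)]],
            [[(100, 22, 40)], [(150, 22, 5)]],
        )
        reads = {
            "A": self.reads("A", [(100, 22, 30), (150, 22, 10)]),
            "B": self.reads("B", [(100, 22, 40)]),
        }
        harmonize_block_groups(locus, reads)
        blocks_b = locus.groups["B"].blocks
        assert len(blocks_b) == 2
        assert blocks_b[1].height == 1 and blocks_b[1].reads[0].is_dummy

    def test_single_block_locus_gains_ten_percent_dummy_block(self):
        locus = two_sample_locus([[(100, 22, 50)]], [[(100, 22, 50)]])
        reads = {s: self.reads(s, [(100, 22, 50)]) for s in ("A", "B")}
        harmonize_block_groups(locus, reads)
        for s in ("A", "B"):
            blocks = locus.groups[s].blocks
            assert len(blocks) == 2
            dummy = [b for b in blocks if b.is_dummy]
            assert len(dummy) == 1
            # 10% of the parent group's raw expression: 0.1 * 50 = 5
            assert dummy[0].height == 5

    def test_two_block_locus_gets_no_dummy_block(self):
        locus = two_sample_locus(
            [[(100, 22, 30)], [(150, 22, 10)]],
            [[(100, 22, 30)], [(150, 22, 10)]],
        )
        reads = {s: self.reads(s, [(100, 22, 30), (150, 22, 10)]) for s in ("A", "B")}
        harmonize_block_groups(locus, reads)
        assert all(not b.is_dummy for g in locus.groups.values() for b in g.blocks)

    def test_block_structure_identical_across_samples(self):
        locus = two_sample_locus(
            [[(100, 22, 30)], [(150, 22, 10)]],
            [[(101, 22, 12)], [(151, 22, 40)]],
        )
        reads = {
            "A": self.reads("A", [(100, 22, 30), (150, 22, 10)]),
            "B": self.reads("B", [(101, 22, 12), (151, 22, 40)]),
        }
        harmonize_block_groups(locus, reads)
        coords_a = [(b.start, b.end) for b in locus.groups["A"].blocks]
        coords_b = [(b.start, b.end) for b in locus.groups["B"].blocks]
        assert coords_a == coords_b
        assert len(coords_a) == len(locus.consensus_coords)

    def test_raw_expression_restored_below_cutoff(self):
        # B's minor block (5 reads, 11%) was filtered away at detection in a
        # deeper context; harmonization restores the raw reads + 1 pseudocount
        locus = two_sample_locus(
            [[(100, 22, 30)], [(150, 22, 10)]],
            [[(100, 22, 60)]],
        )
        reads = {
            "A": self.reads("A", [(100, 22, 30), (150, 22, 10)]),
            "B": self.reads("B", [(100, 22, 60), (150, 22, 5)]),
        }
        harmonize_block_groups(locus, reads)
        minor_b = locus.groups["B"].blocks[1]
        assert minor_b.height == 6  # 5 raw + 1 dummy pseudocount

    def test_idempotent(self):
        locus = two_sample_locus([[(100, 22, 50)]], [[(100, 22, 50)]])
        reads = {s: self.reads(s, [(100, 22, 50)]) for s in ("A", "B")}
        harmonize_block_groups(locus, reads)
        snapshot = [
            (s, [(b.start, b.end, b.height, b.is_dummy)
                 for b in locus.groups[s].blocks])
            for s in locus.samples
        ]
        harmonize_block_groups(locus, {})  # no reads needed: must be a no-op
        assert snapshot == [
            (s, [(b.start, b.end, b.height, b.is_dummy)
                 for b in locus.groups[s].blocks])
            for s in locus.samples
        ]

    def test_missing_sample_reads_is_hard_error(self):
        locus = two_sample_locus([[(100, 22, 50)]], [[(100, 22, 50)]])
        with pytest.raises(ValueError, match="no raw reads"):
            harmonize_block_groups(locus, {"A": self.reads("A", [(100, 22, 50)])})
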
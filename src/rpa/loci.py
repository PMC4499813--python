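"""Cross-sample locus selection and block-group harmonization.

Comparing read profiles across samples requires (a) restricting to genomic
loci where a profile is observed in *every* sample, and (b) giving every
sample's profile the same number of blocks at the same coordinates.  The
harmonization places, for each consensus block coordinate, a single dummy
read in every sample and then pulls in all of that sample's raw reads mapping
at the coordinate — so block expressions are raw again, undoing the fixed
relative 10% cut-off applied during block detection.  Loci where every
profile has a single block additionally receive a shared dummy block
(identical coordinates on all samples, expression 10% of the parent group)
because the profile aligner needs at least two blocks for a meaningful
comparison; being identical everywhere, the dummy block never drives
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import Block, BlockGroup, MappedRead

__all__ = ["LocusTable", "select_common_loci", "consensus_block_coordinates",
           "harmonize_block_groups"]

DUMMY_BLOCK_GAP = 10  # nt between parent block group and appended dummy block
DUMMY_BLOCK_WIDTH = 20


@dataclass
class LocusTable:
    """One genomic locus with (eventually harmonized) block groups for all
    samples."""

    locus_id: int
    chrom: str
    start: int
    end: int
    strand: str
    samples: list[str]
    groups: dict[str, BlockGroup]  # sample -> block group
    consensus_coords: list[tuple[int, int]] = field(default_factory=list)
    harmonized: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def select_common_loci(
    groups_by_sample: dict[str, list[BlockGroup]],
    samples: list[str] | None = None,
) -> list[LocusTable]:
    """Find loci where an overlapping block group exists in every sample.

    Block groups on the same chromosome and strand that overlap by >= 1 nt are
    chained into a candidate region; the region becomes a locus iff every
    required sample contributes at least one group.  A sample's groups within
    one locus are merged into a single profile; the locus span is the union of
    member spans.
    """
    required = list(samples) if samples is not None else sorted(groups_by_sample)
    entries: dict[tuple[str, str], list[BlockGroup]] = {}
    for sample in required:
        for g in groups_by_sample.get(sample, []):
            entries.setdefault((g.chrom, g.strand), []).append(g)

    loci: list[LocusTable] = []
    locus_id = 0
    for (chrom, strand) in sorted(entries):
        members = sorted(entries[(chrom, strand)], key=lambda g: (g.start, g.end))
        component: list[BlockGroup] = []
        cur_end = -1
        for g in members + [None]:  # sentinel flushes the last component
            if g is not None and (not component or g.start < cur_end):
                component.append(g)
                cur_end = max(cur_end, g.end)
                continue
            if component:
                present = {m.sample for m in component}
                if all(s in present for s in required):
                    locus_id += 1
                    merged: dict[str, BlockGroup] = {}
                    for m in component:
                        if m.sample not in merged:
                            merged[m.sample] = BlockGroup(
                                chrom, m.start, m.end, strand, sample=m.sample
                            )
                        merged[m.sample].blocks.extend(m.blocks)
                    for bg in merged.values():
                        bg.sort_blocks()
                        bg.recompute_span()
                    loci.append(
                        LocusTable(
                            locus_id=locus_id,
                            chrom=chrom,
                            start=min(m.start for m in component),
                            end=max(m.end for m in component),
                            strand=strand,
                            samples=list(required),
                            groups=merged,
                        )
                    )
            if g is not None:
                component = [g]
                cur_end = g.end
    return loci


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def consensus_block_coordinates(
    locus: LocusTable, min_reciprocal_overlap: float = 0.90
) -> list[tuple[int, int]]:
    """Greedy merge of member blocks into consensus coordinates.

    Blocks are processed by descending height (determinism); a block joins an
    existing consensus coordinate when their reciprocal overlap is >= 90%,
    otherwise it seeds a new coordinate whose interval is the seed block's.
    Any two output coordinates therefore overlap by < 90%.
    """
    blocks: list[tuple[int, Block]] = []
    for sample in locus.samples:
        for b in locus.groups[sample].blocks:
            if not b.is_dummy:
                blocks.append((b.height, b))
    blocks.sort(key=lambda hb: (-hb[0], hb[1].start, hb[1].end))

    coords: list[tuple[int, int]] = []
    for _, b in blocks:
        iv = (b.start, b.end)
        best, best_ov = None, min_reciprocal_overlap
        for c in coords:
            ov = _reciprocal_overlap(iv, c)
            if ov >= best_ov:
                best, best_ov = c, ov
        if best is None:
            coords.append(iv)
    coords.sort()
    locus.consensus_coords = coords
    return coords


def harmonize_block_groups(
    locus: LocusTable,
    reads_by_sample: dict[str, list[MappedRead]],
    dummy_block_fraction: float = 0.10,
) -> LocusTable:
    """Rebuild every sample's block group on the consensus coordinates.

    For each sample and consensus coordinate, the new block holds one dummy
    read (count 1, flagged) plus all of that sample's raw reads whose midpoint
    falls inside the coordinate; block expressions are thus raw counts plus
    the single pseudocount.  Single-block loci get the shared adjacent dummy
    block.  Harmonizing an already-harmonized locus is a no-op.
    """
    if locus.harmonized:
        return locus
    if not locus.consensus_coords:
        consensus_block_coordinates(locus)
    coords = locus.consensus_coords

    for sample in locus.samples:
        if sample not in reads_by_sample:
            raise ValueError(f"no raw reads supplied for sample {sample!r}")

    single_block = len(coords) == 1
    dummy_start = max(e for _, e in coords) + DUMMY_BLOCK_GAP
    dummy_end = dummy_start + DUMMY_BLOCK_WIDTH

    for sample in locus.samples:
        sample_reads = [
            r for r in reads_by_sample[sample]
            if r.chrom == locus.chrom and r.strand == locus.strand
        ]
        blocks: list[Block] = []
        for (cs, ce) in coords:
            reads = [
                MappedRead(locus.chrom, cs, ce, locus.strand, 1, sample, is_dummy=True)
            ]
            reads.extend(r for r in sample_reads if cs <= r.midpoint < ce)
            blocks.append(Block(start=cs, end=ce, reads=reads))
        group = BlockGroup(locus.chrom, 0, 0, locus.strand, blocks=blocks, sample=sample)
        if single_block:
            parent_total = sum(b.non_dummy_height for b in blocks)
            k = max(1, math.ceil(dummy_block_fraction * parent_total))
            dummy_reads = [
                MappedRead(locus.chrom, dummy_start, dummy_end, locus.strand, 1,
                           sample, is_dummy=True)
                for _ in range(k)
            ]
            blocks.append(Block(start=dummy_start, end=dummy_end, reads=dummy_reads,
                                is_dummy=True))
        group.sort_blocks()
        group.recompute_span()
        locus.groups[sample] = group

    locus.start = min(g.start for g in locus.groups.values())
    locus.end = max(g.end for g in locus.groups.values())
    locus.harmonized = True
    return locus
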
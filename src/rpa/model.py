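"""Core data model: mapped reads, read blocks and block groups.

A *block* is a stack of short-RNA reads with similar start/stop positions,
analogous to one processed RNA fragment (a mature miRNA arm, a tRNA half,
...).  A *block group* (synonym: read profile) is the ordered set of blocks
observed at one genomic locus in one sample; it is the unit that is compared
across samples.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["MappedRead", "Block", "BlockGroup"]


@dataclass(frozen=True, slots=True)
class MappedRead:
    """One aligned (possibly collapsed) short read.

    ``count`` is the read multiplicity after collapsing identical reads.
    ``is_dummy`` marks pseudo-reads inserted by cross-sample harmonization;
    dummy reads always carry count 1 and are excluded from entropy and
    size-factor computations.
    """

    chrom: str
    start: int
    end: int
    strand: str
    count: int = 1
    sample: str = ""
    is_dummy: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read has start >= end: {self.start} >= {self.end}")
        if self.count < 1:
            raise ValueError(f"read count must be >= 1, got {self.count}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol: {self.strand!r}")
        if self.is_dummy and self.count != 1:
            raise ValueError("dummy reads must have count == 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(slots=True)
class Block:
    """A stack of reads forming one processed-fragment signal."""

    start: int
    end: int
    reads: list[MappedRead] = field(default_factory=list)
    is_dummy: bool = False

    @property
    def height(self) -> int:
        """Total read count in the block (dummy reads included)."""
        return sum(r.count for r in self.reads)

    @property
    def non_dummy_height(self) -> int:
        return sum(r.count for r in self.reads if not r.is_dummy)

    @classmethod
    def from_reads(cls, reads: list[MappedRead], is_dummy: bool = False) -> "Block":
        if not reads:
            raise ValueError("cannot build a block from zero reads")
        return cls(
            start=min(r.start for r in reads),
            end=max(r.end for r in reads),
            reads=list(reads),
            is_dummy=is_dummy,
        )


@dataclass(slots=True)
class BlockGroup:
    """A read profile: ordered blocks at one locus in one sample."""

    chrom: str
    start: int
    end: int
    strand: str
    blocks: list[Block] = field(default_factory=list)
    sample: str = ""

    @property
    def total_reads(self) -> int:
        return sum(b.height for b in self.blocks)

    @property
    def non_dummy_blocks(self) -> list[Block]:
        return [b for b in self.blocks if not b.is_dummy]

    @property
    def non_dummy_span(self) -> int:
        real = self.non_dummy_blocks
        if not real:
            return 0
        return max(b.end for b in real) - min(b.start for b in real)

    def rel_height(self, block: Block) -> float:
        """Block height relative to the group total."""
        total = self.total_reads
        if total == 0:
            raise ValueError("empty block group has no relative heights")
        return block.height / total

    def sort_blocks(self) -> None:
        self.blocks.sort(key=lambda b: (b.start, b.end))

    def recompute_span(self) -> None:
        """Reset group span to the envelope of its current blocks."""
        if not self.blocks:
            raise ValueError("cannot recompute span of an empty group")
        self.start = min(b.start for b in self.blocks)
        self.end = max(b.end for b in self.blocks)

    def shifted(self, offset: int) -> "BlockGroup":
        """Translate the whole group by ``offset`` nucleotides."""
        return BlockGroup(
            chrom=self.chrom,
            start=self.start + offset,
            end=self.end + offset,
            strand=self.strand,
            sample=self.sample,
            blocks=[
                Block(
                    start=b.start + offset,
                    end=b.end + offset,
                    reads=[
                        replace(r, start=r.start + offset, end=r.end + offset)
                        for r in b.reads
                    ],
                    is_dummy=b.is_dummy,
                )
                for b in self.blocks
            ],
        )
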
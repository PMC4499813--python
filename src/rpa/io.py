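"""Reading and writing of external formats.

All coordinates are normalized to 0-based half-open at this boundary: BED is
consumed natively, GFF (1-based inclusive) is converted on read.  Strand is
never silently discarded — every interval query states its strand mode.

Mapped reads come from coordinate files (BED6, count in the score column) or
from BAM via :mod:`pysam`.  Block groups round-trip through a blockbuster-like
tab-separated text format; one header line per group followed by one line per
block, with the constituent reads carried in a compact extra column so that
serialization is lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .model import Block, BlockGroup, MappedRead

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "read_mapped_reads",
    "read_annotations",
    "serialize_block_groups",
    "parse_block_groups",
    "write_reads_bed",
]

ANNOTATION_ROLES = ("ncrna", "region", "segmentation", "tss")


@dataclass(frozen=True, slots=True)
class AnnotationInterval:
    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' when the source has no strand
    label: str


@dataclass
class AnnotationSet:
    """Strand-aware interval indexes for ncRNA, genomic-region, chromatin-state
    and TSS annotations.

    TSS entries are 1-nt points; all other zero-length intervals are rejected.
    Identical intervals are deduplicated on load, so overlap queries return
    each source interval once.
    """

    ncrna: dict[str, IntervalTree] = field(default_factory=dict)
    region: dict[str, IntervalTree] = field(default_factory=dict)
    segmentation: dict[str, IntervalTree] = field(default_factory=dict)
    tss: list[AnnotationInterval] = field(default_factory=list)

    def _tree(self, role: str, chrom: str) -> IntervalTree | None:
        return getattr(self, role).get(chrom)

    def overlapping(
        self, role: str, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[AnnotationInterval]:
        """Intervals of ``role`` overlapping [start, end) by >= 1 nt.

        ``strand=None`` ignores strand; otherwise only same-strand intervals
        (and strandless '.' intervals) are returned.
        """
        tree = self._tree(role, chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [a for a in hits if a.strand in (strand, ".")]
        return sorted(hits, key=lambda a: (a.start, a.end, a.label))


def _bed_fields(line: str, lineno: int, path: str, min_cols: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated toy files
        fields = line.split()
    if len(fields) < min_cols:
        raise ValueError(f"{path}:{lineno}: expected >= {min_cols} BED columns, got {len(fields)}")
    return fields


def _parse_coords(fields: list[str], lineno: int, path: str) -> tuple[str, int, int]:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if end < start:
        raise ValueError(f"{path}:{lineno}: end < start ({end} < {start})")
    return fields[0], start, end


def _iter_data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_mapped_reads(
    path: str | Path,
    format: str = "bed",
    min_accuracy: float = 0.85,
    sample: str = "",
) -> list[MappedRead]:
    """Load mapped reads with 0-based half-open coordinates.

    BED6 carries the collapsed read multiplicity in the score column.  For BAM,
    reads flagged secondary/supplementary are dropped (only uniquely mapped
    reads are profiled), and alignment identity computed from the NM edit
    distance must reach ``min_accuracy``; records without NM are kept and
    tallied.  BED carries no accuracy information, so there the filter is a
    no-op and a warning is logged.
    """
    if not 0.0 <= min_accuracy <= 1.0:
        raise ValueError("min_accuracy must lie in [0, 1]")
    if format == "bed":
        if min_accuracy > 0:
            logger.warning(
                "BED input carries no mapping-accuracy information; "
                "min_accuracy=%.2f filter is a no-op", min_accuracy,
            )
        return _read_bed_reads(path, sample)
    if format == "bam":
        return _read_bam_reads(path, min_accuracy, sample)
    raise ValueError(f"unknown read format: {format!r}")


def _read_bed_reads(path: str | Path, sample: str) -> list[MappedRead]:
    reads: list[MappedRead] = []
    for lineno, line in _iter_data_lines(path):
        fields = _bed_fields(line, lineno, str(path), 6)
        chrom, start, end = _parse_coords(fields, lineno, str(path))
        try:
            count = int(fields[4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer read count") from exc
        strand = fields[5]
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        try:
            reads.append(MappedRead(chrom, start, end, strand, count, sample))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return reads


def _read_bam_reads(path: str | Path, min_accuracy: float, sample: str) -> list[MappedRead]:
    import pysam

    reads: list[MappedRead] = []
    no_accuracy_info = 0
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            aligned = rec.query_alignment_length
            if aligned == 0:
                continue
            if rec.has_tag("NM"):
                identity = (aligned - rec.get_tag("NM")) / aligned
                if identity < min_accuracy:
                    continue
            else:
                no_accuracy_info += 1
            strand = "-" if rec.is_reverse else "+"
            reads.append(
                MappedRead(rec.reference_name, rec.reference_start, rec.reference_end,
                           strand, 1, sample)
            )
    if no_accuracy_info:
        logger.info("%d BAM records lacked an NM tag and were kept unfiltered", no_accuracy_info)
    return reads


def read_annotations(paths: dict[str, str | Path], format: str = "bed") -> AnnotationSet:
    """Load annotation files into strand-aware interval indexes.

    ``paths`` maps a role in {ncrna, region, segmentation, tss} to a file.
    The feature label is the BED name column, or the GFF type column.
    """
    ann = AnnotationSet()
    for role, path in paths.items():
        if role not in ANNOTATION_ROLES:
            raise ValueError(f"unknown annotation role: {role!r}")
        intervals = list(_read_annotation_file(path, format))
        seen: set[AnnotationInterval] = set()
        for iv in intervals:
            if iv in seen:
                continue
            seen.add(iv)
            if role == "tss":
                if iv.end - iv.start > 1:
                    # point feature: collapse to the 5'-most nucleotide
                    pos = iv.start if iv.strand != "-" else iv.end - 1
                    iv = AnnotationInterval(iv.chrom, pos, pos + 1, iv.strand, iv.label)
                ann.tss.append(iv)
            else:
                if iv.end == iv.start:
                    raise ValueError(f"zero-length interval for role {role}: {iv}")
                getattr(ann, role).setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, iv
                )
    return ann


def _read_annotation_file(path: str | Path, format: str) -> Iterator[AnnotationInterval]:
    if format == "bed":
        for lineno, line in _iter_data_lines(path):
            fields = _bed_fields(line, lineno, str(path), 3)
            chrom, start, end = _parse_coords(fields, lineno, str(path))
            label = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            yield AnnotationInterval(chrom, start, end, strand, label)
    elif format == "gff":
        for lineno, line in _iter_data_lines(path):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 GFF columns")
            chrom, _, ftype = fields[0], fields[1], fields[2]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start")
            strand = fields[6] if fields[6] in ("+", "-") else "."
            # GFF is 1-based inclusive
            yield AnnotationInterval(chrom, start1 - 1, end1, strand, ftype)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")


# ---------------------------------------------------------------------------
# block-group text format


def _reads_spec(block: Block) -> str:
    parts = [
        f"{r.start}:{r.end - r.start}:{r.count}:{1 if r.is_dummy else 0}"
        for r in sorted(block.reads, key=lambda r: (r.start, r.end, r.is_dummy))
    ]
    return ",".join(parts) if parts else "."


def serialize_block_groups(groups: Iterable[BlockGroup], path: str | Path) -> None:
    """Write block groups as tab-separated text (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tid\ttotal\tstrand\tn_blocks\n")
        for idx, g in enumerate(groups, start=1):
            gid = f"{g.sample or 'bg'}|{idx}"
            fh.write(
                f">{g.chrom}\t{g.start}\t{g.end}\t{gid}\t{g.total_reads}\t"
                f"{g.strand}\t{len(g.blocks)}\n"
            )
            for bn, b in enumerate(g.blocks, start=1):
                fh.write(
                    f"{bn}\t{b.start}\t{b.end}\t{b.height}\t"
                    f"{1 if b.is_dummy else 0}\t{_reads_spec(b)}\n"
                )


def parse_block_groups(path: str | Path) -> list[BlockGroup]:
    """Inverse of :func:`serialize_block_groups`."""
    groups: list[BlockGroup] = []
    current: BlockGroup | None = None
    expected_blocks = 0
    for lineno, line in _iter_data_lines(path):
        fields = line.rstrip("\n").split("\t")
        if line.startswith(">"):
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: malformed group header")
            chrom = fields[0][1:]
            start, end = int(fields[1]), int(fields[2])
            gid, total, strand, nblocks = fields[3], int(fields[4]), fields[5], int(fields[6])
            sample = gid.rsplit("|", 1)[0] if "|" in gid else ""
            current = BlockGroup(chrom, start, end, strand, sample=sample)
            expected_blocks = nblocks
            groups.append(current)
        else:
            if current is None:
                raise ValueError(f"{path}:{lineno}: block line before any group header")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: malformed block line")
            try:
                bstart, bend = int(fields[1]), int(fields[2])
                height, is_dummy = int(fields[3]), bool(int(fields[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed block line") from exc
            reads: list[MappedRead] = []
            if fields[5] != ".":
                for token in fields[5].split(","):
                    try:
                        rs, rl, rc, rd = (int(x) for x in token.split(":"))
                    except ValueError as exc:
                        raise ValueError(f"{path}:{lineno}: malformed reads spec") from exc
                    reads.append(
                        MappedRead(current.chrom, rs, rs + rl, current.strand,
                                   rc, current.sample, bool(rd))
                    )
            block = Block(start=bstart, end=bend, reads=reads, is_dummy=is_dummy)
            if reads and block.height != height:
                raise ValueError(
                    f"{path}:{lineno}: block height {height} does not match reads"
                )
            current.blocks.append(block)
    if groups and expected_blocks and len(groups[-1].blocks) != expected_blocks:
        raise ValueError(f"{path}: last group truncated")
    return groups


def write_reads_bed(reads: Iterable[MappedRead], path: str | Path) -> None:
    """Write collapsed reads as BED6 (count in the score column)."""
    with open(path, "w") as fh:
        for i, r in enumerate(sorted(reads, key=lambda r: (r.chrom, r.start, r.end))):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i + 1}\t{r.count}\t{r.strand}\n")
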
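"""Grouping of mapped reads into loci and read blocks.

Closely spaced reads (< 50 nt apart by default) are assigned to one locus;
within a locus, blocks are detected by an iterative Gaussian-peak procedure:
every read contributes a Gaussian density centred at its midpoint with
standard deviation ``scale * read_length``, weighted by its count.  The
highest summed-density peak seeds a block, reads whose midpoint falls within
the peak's capture window join it and are removed, and the procedure repeats.
Blocks below a relative 10% expression cut-off (relative to the block-group
total) are dropped, which keeps profiles from samples sequenced to different
depths comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import Block, BlockGroup, MappedRead

__all__ = ["BlockParams", "cluster_reads_into_loci", "detect_blocks", "build_block_groups"]


@dataclass(frozen=True)
class BlockParams:
    """Locus/block detection parameters.

    Defaults follow the established small-RNA profiling settings: loci split
    at gaps >= 50 nt, block groups need >= 10 reads, blocks need >= 10% of the
    group's reads (relative mode), Gaussian sigma = 0.5 x read length.
    """

    max_gap: int = 50
    min_cluster_height: int = 10
    rel_block_cutoff: float = 0.10
    scale: float = 0.5
    abs_block_height: int | None = None  # absolute-threshold mode when set
    capture_factor: float = 2.0  # capture window = +/- capture_factor*scale*len


def cluster_reads_into_loci(
    reads: list[MappedRead], max_gap: int = 50
) -> list[list[MappedRead]]:
    """Partition reads of one chromosome+strand into loci.

    Consecutive reads whose gap (next.start - current_max_end) is < ``max_gap``
    share a locus.  Input must be sorted by start.
    """
    if not reads:
        return []
    for a, b in zip(reads, reads[1:]):
        if b.start < a.start:
            raise ValueError("reads must be sorted by start position")
    chroms = {(r.chrom, r.strand) for r in reads}
    if len(chroms) > 1:
        raise ValueError("cluster_reads_into_loci expects a single chromosome and strand")

    clusters: list[list[MappedRead]] = [[reads[0]]]
    cur_end = reads[0].end
    for r in reads[1:]:
        if r.start - cur_end < max_gap:
            clusters[-1].append(r)
        else:
            clusters.append([r])
        cur_end = max(cur_end, r.end)
    return clusters


def _density(reads: list[MappedRead], positions: np.ndarray, scale: float) -> np.ndarray:
    """Summed, count-weighted Gaussian read density on integer positions."""
    dens = np.zeros(len(positions), dtype=float)
    for r in reads:
        sigma = max(scale * r.length, 0.5)
        z = (positions - r.midpoint) / sigma
        dens += r.count * np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
    return dens


def detect_blocks(
    cluster: list[MappedRead],
    scale: float = 0.5,
    min_block_height: int = 1,
    capture_factor: float = 2.0,
) -> list[Block]:
    """Iterative Gaussian-peak block detection on one read cluster.

    Peaks are evaluated on integer genomic positions only; ties between
    equal-density peaks break to the leftmost position for determinism.
    A read joins the current peak when its midpoint lies within
    ``+/- capture_factor * scale * read_length`` of the peak centre.  Iteration
    stops when the best remaining peak captures fewer than
    ``min_block_height`` reads.
    """
    if not cluster:
        raise ValueError("cannot detect blocks in an empty cluster")
    remaining = list(cluster)
    lo = min(r.start for r in remaining)
    hi = max(r.end for r in remaining)
    positions = np.arange(lo, hi + 1)

    blocks: list[Block] = []
    while remaining:
        dens = _density(remaining, positions, scale)
        peak = positions[int(np.argmax(dens))]  # argmax returns leftmost maximum
        captured = [
            r for r in remaining
            if abs(r.midpoint - peak) <= capture_factor * scale * r.length
        ]
        if not captured or sum(r.count for r in captured) < min_block_height:
            break
        blocks.append(Block.from_reads(captured))
        captured_ids = {id(r) for r in captured}
        remaining = [r for r in remaining if id(r) not in captured_ids]
    blocks.sort(key=lambda b: (b.start, b.end))
    return blocks


def build_block_groups(
    reads_by_sample: dict[str, list[MappedRead]],
    params: BlockParams = BlockParams(),
) -> list[BlockGroup]:
    """Full read -> block-group conversion for every sample.

    Per sample: reads are split by chromosome and strand, clustered into loci,
    blocks are detected, clusters with fewer than ``min_cluster_height`` total
    reads are dropped, and blocks below the relative cut-off (measured against
    the pre-filter cluster total) are removed.  Group spans are recomputed from
    the surviving blocks.
    """
    groups: list[BlockGroup] = []
    for sample in sorted(reads_by_sample):
        by_track: dict[tuple[str, str], list[MappedRead]] = {}
        for r in reads_by_sample[sample]:
            by_track.setdefault((r.chrom, r.strand), []).append(r)
        for (chrom, strand), track_reads in sorted(by_track.items()):
            track_reads.sort(key=lambda r: (r.start, r.end))
            for cluster in cluster_reads_into_loci(track_reads, params.max_gap):
                total = sum(r.count for r in cluster)
                if total < params.min_cluster_height:
                    continue
                if params.abs_block_height is not None:
                    min_h = params.abs_block_height
                else:
                    min_h = 1
                blocks = detect_blocks(
                    cluster, params.scale, min_h, params.capture_factor
                )
                if params.abs_block_height is None:
                    blocks = [
                        b for b in blocks
                        if b.height / total >= params.rel_block_cutoff
                    ]
                if not blocks:
                    continue
                group = BlockGroup(chrom, 0, 0, strand, blocks=blocks, sample=sample)
                group.recompute_span()
                groups.append(group)
    return groups
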
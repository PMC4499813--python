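"""Annotation assignment and genomic enrichment statistics.

Loci are labelled against known ncRNA annotations (>= 1 nt overlap) and
genomic regions (> 50% overlap, maximum-overlap wins, else intergenic).
Enrichment of a set of intervals in a genomic feature (e.g. a chromatin
state) uses the dart-throwing null: each interval hits the feature with
probability equal to the feature's merged genome fraction, and the upper
binomial tail gives the p-value.  A strand-aware metaprofile around
transcription start sites bins percentage overlap in 20-nt bins across a
+/- 1000 nt window, flipping minus-strand TSS so downstream is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .io import AnnotationInterval, AnnotationSet
from .model import BlockGroup

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "annotate_interval", "binomial_enrichment",
           "tss_profile", "merged_length"]


@dataclass
class EnrichmentResult:
    feature: str
    n: int
    observed: int
    null_fraction: float
    p_value: float


def annotate_interval(
    bg: BlockGroup, ann: AnnotationSet
) -> dict[str, str | None]:
    """Assign an ncRNA class and a genomic-region label to a block group.

    ncRNA: any >= 1 nt same-strand overlap makes the locus "annotated"; the
    class is the overlapping annotation's, ties broken by larger overlap.
    Region: the label covering > 50% of the group wins (maximum overlap among
    competing labels); otherwise "intergenic".
    """
    span = bg.end - bg.start

    def ov_len(a: AnnotationInterval) -> int:
        return min(a.end, bg.end) - max(a.start, bg.start)

    ncrna_hits = ann.overlapping("ncrna", bg.chrom, bg.start, bg.end, strand=bg.strand)
    ncrna_class: str | None = None
    if ncrna_hits:
        ncrna_class = max(ncrna_hits, key=lambda a: (ov_len(a), a.label)).label

    region_cover: dict[str, int] = {}
    for a in ann.overlapping("region", bg.chrom, bg.start, bg.end, strand=bg.strand):
        region_cover[a.label] = region_cover.get(a.label, 0) + ov_len(a)
    region = "intergenic"
    if region_cover:
        best = max(sorted(region_cover), key=lambda k: region_cover[k])
        if region_cover[best] / span > 0.5:
            region = best
    return {"ncrna": ncrna_class, "region": region}


def merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered length after merging overlapping intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def binomial_enrichment(
    intervals: list[tuple[str, int, int]],
    feature: list[tuple[str, int, int]],
    genome_size: int,
    label: str = "feature",
) -> EnrichmentResult:
    """Dart-model enrichment of query intervals in a feature set.

    Null success probability = merged feature length / genome size; observed =
    queries overlapping the feature by >= 1 nt; p-value is the upper binomial
    tail P(X >= observed).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in feature:
        by_chrom.setdefault(chrom, []).append((s, e))
    cov = sum(merged_length(ivs) for ivs in by_chrom.values())
    n = len(intervals)
    if cov == 0:
        logger.warning("zero-length feature set %r; p-value = 1", label)
        return EnrichmentResult(label, n, 0, 0.0, 1.0)
    if cov > genome_size:
        raise ValueError("total feature length exceeds genome_size")
    p_null = cov / genome_size

    merged = {c: sorted(ivs) for c, ivs in by_chrom.items()}

    def hits(chrom: str, s: int, e: int) -> bool:
        for fs, fe in merged.get(chrom, []):
            if fs < e and s < fe:
                return True
            if fs >= e:
                break
        return False

    observed = sum(1 for chrom, s, e in intervals if hits(chrom, s, e))
    p_value = float(binom.sf(observed - 1, n, p_null)) if n else 1.0
    return EnrichmentResult(label, n, observed, p_null, min(1.0, max(p_value, 0.0)))


def tss_profile(
    intervals: list[tuple[str, int, int, str]],
    tss: list[AnnotationInterval],
    window: int = 1000,
    bin_size: int = 20,
) -> dict[str, np.ndarray]:
    """Strand-aware mean percent overlap per bin around TSS.

    The 2*window-nt window is split into ``2*window/bin_size`` bins; for every
    (interval, TSS) pair with the interval inside the window, each bin records
    the percent of its bin_size nt covered by the interval.  Profiles are
    averaged separately over sense pairs (interval on the TSS strand) and
    antisense pairs; an interval near two TSS contributes to both.  For
    minus-strand TSS coordinates are flipped so that positive bins are always
    downstream of transcription.
    """
    n_bins = (2 * window) // bin_size
    edges = np.arange(-window, window + 1, bin_size)
    tracks = {"sense": np.zeros(n_bins), "antisense": np.zeros(n_bins)}
    counts = {"sense": 0, "antisense": 0}

    for t in tss:
        t_pos = t.start
        for chrom, s, e, strand in intervals:
            if chrom != t.chrom:
                continue
            if t.strand == "-":
                rel_s, rel_e = t_pos - e + 1, t_pos - s + 1
            else:
                rel_s, rel_e = s - t_pos, e - t_pos
            if rel_e <= -window or rel_s >= window:
                continue
            track = "sense" if strand == t.strand else "antisense"
            prof = np.zeros(n_bins)
            for b in range(n_bins):
                lo, hi = edges[b], edges[b + 1]
                ov = min(hi, rel_e) - max(lo, rel_s)
                prof[b] = 100.0 * max(0, ov) / bin_size
            tracks[track] += prof
            counts[track] += 1

    out = {}
    for k in tracks:
        out[k] = tracks[k] / counts[k] if counts[k] else tracks[k]
    out["bin_start"] = edges[:-1].astype(float)
    out["n_sense"] = counts["sense"]
    out["n_antisense"] = counts["antisense"]
    return out
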
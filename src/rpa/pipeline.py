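"""End-to-end orchestration: reads -> block groups -> loci -> differential and
coherent processing calls.

The pipeline is a pure function of its inputs and seed: block groups are
built per sample, loci observed in every sample are selected and harmonized,
each locus gets an alignment score matrix, bootstrap-supported clustering
with the cluster score X, a coherence call, and candidates (X >= 0.15) are
validated on depth-normalized block expression.  Size factors are computed
once from the block counts of all analyzed loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import BlockParams, build_block_groups
from .cluster import (DEFAULT_SCALES, ClusterResult, ScoreMatrix,
                      bootstrap_cluster, compute_cluster_score,
                      compute_score_matrix)
from .coherent import CPCall, call_cpl, classify_short_precise
from .loci import LocusTable, harmonize_block_groups, select_common_loci
from .model import MappedRead
from .validate import (DPVerdict, SizeFactors, compute_size_factors,
                       locus_block_counts, validate_dpl)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "LocusResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    mode: str = "combined"  # 'combined' uses replicate-consistency checks
    seed: int = 17
    # block grouping
    max_gap: int = 50
    min_cluster_height: int = 10
    rel_block_cutoff: float = 0.10
    scale: float = 0.5
    # differential processing
    n_boot: int = 500
    boot_scales: tuple[float, ...] = DEFAULT_SCALES
    boot_method: str = "au"
    x_threshold: float = 0.15
    cluster_alpha: float = 0.05
    min_cluster_size: int = 4
    # validation
    alpha: float = 0.05
    fisher_mc_tables: int = 10_000
    # coherence
    cpl_threshold: float = 0.8
    entropy_threshold: float = 2.0
    short_length: int = 40

    def block_params(self) -> BlockParams:
        return BlockParams(
            max_gap=self.max_gap,
            min_cluster_height=self.min_cluster_height,
            rel_block_cutoff=self.rel_block_cutoff,
            scale=self.scale,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "boot_scales" in raw:
            raw["boot_scales"] = tuple(raw["boot_scales"])
        return cls(**raw)


@dataclass
class LocusResult:
    locus: LocusTable
    score_matrix: ScoreMatrix
    clustering: ClusterResult
    cp_call: CPCall
    verdict: DPVerdict | None
    short_precise_fraction: float


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    loci: list[LocusResult]
    size_factors: SizeFactors | None
    config: PipelineConfig

    def write_summary(self, path: str | Path) -> None:
        self.summary.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    reads_by_sample: dict[str, list[MappedRead]],
    replicate_map: dict[str, str] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run every stage on in-memory reads.

    ``replicate_map`` maps sample id -> cell line and is required in combined
    mode (every cell line must then have exactly two replicates).
    """
    if config.mode == "combined":
        if replicate_map is None:
            raise ValueError("combined mode requires a replicate map")
        by_line: dict[str, int] = {}
        for s in reads_by_sample:
            by_line[replicate_map[s]] = by_line.get(replicate_map[s], 0) + 1
        bad = {k: v for k, v in by_line.items() if v != 2}
        if bad:
            raise ValueError(f"combined mode needs exactly 2 replicates per line: {bad}")

    logger.info("building block groups for %d samples", len(reads_by_sample))
    groups = build_block_groups(reads_by_sample, config.block_params())
    by_sample: dict[str, list] = {s: [] for s in reads_by_sample}
    for g in groups:
        by_sample[g.sample].append(g)

    loci = select_common_loci(by_sample)
    logger.info("selected %d loci observed in all %d samples",
                len(loci), len(reads_by_sample))

    locus_results: list[LocusResult] = []
    count_blocks: list[np.ndarray] = []
    for locus in loci:
        harmonize_block_groups(locus, reads_by_sample)
        count_blocks.append(locus_block_counts(locus, include_dummy_read=False))

    size_factors: SizeFactors | None = None
    if loci:
        samples = loci[0].samples
        size_factors = compute_size_factors(np.vstack(count_blocks), samples)

    for locus in loci:
        matrix = compute_score_matrix(locus)
        locus_seed = (config.seed * 9_973 + locus.locus_id) % (2**31)
        clustering = bootstrap_cluster(
            matrix,
            n_boot=config.n_boot,
            scales=config.boot_scales,
            seed=locus_seed,
            method=config.boot_method,
        )
        compute_cluster_score(
            matrix,
            clustering,
            replicate_map=replicate_map,
            mode=config.mode,
            alpha=config.cluster_alpha,
            x_threshold=config.x_threshold,
            min_cluster_size=config.min_cluster_size,
        )
        cp = call_cpl(matrix, threshold=config.cpl_threshold, locus_id=locus.locus_id)
        sp_frac = float(np.mean([
            classify_short_precise(
                locus.groups[s], config.entropy_threshold, config.short_length
            )
            for s in locus.samples
        ]))
        verdict = None
        if clustering.candidate and size_factors is not None:
            verdict = validate_dpl(
                locus,
                clustering,
                size_factors,
                alpha=config.alpha,
                replicate_map=replicate_map,
                mode=config.mode,
                seed=locus_seed,
                n_mc=config.fisher_mc_tables,
            )
        locus_results.append(
            LocusResult(locus, matrix, clustering, cp, verdict, sp_frac)
        )

    summary = pd.DataFrame(
        {
            "locus_id": [lr.locus.locus_id for lr in locus_results],
            "chrom": [lr.locus.chrom for lr in locus_results],
            "start": [lr.locus.start for lr in locus_results],
            "end": [lr.locus.end for lr in locus_results],
            "strand": [lr.locus.strand for lr in locus_results],
            "n_consensus_blocks": [
                len(lr.locus.consensus_coords) for lr in locus_results
            ],
            "cluster_score": [round(lr.clustering.cluster_score, 6)
                              for lr in locus_results],
            "candidate_dpl": [lr.clustering.candidate for lr in locus_results],
            "validated_dpl": [
                bool(lr.verdict.is_dpl) if lr.verdict is not None else False
                for lr in locus_results
            ],
            "mean_alignment_score": [round(lr.cp_call.mean_score, 6)
                                     for lr in locus_results],
            "cpl": [lr.cp_call.is_cpl for lr in locus_results],
            "short_precise_fraction": [lr.short_precise_fraction
                                       for lr in locus_results],
            "fisher_min_p": [
                _min_offdiag_p(lr.verdict) for lr in locus_results
            ],
        }
    )
    # informational BH q-values across candidate loci; never used in verdicts
    summary["fisher_min_q"] = _bh_adjust(summary["fisher_min_p"].to_numpy())
    return PipelineResult(summary=summary, loci=locus_results,
                          size_factors=size_factors, config=config)


def _min_offdiag_p(verdict: DPVerdict | None) -> float:
    if verdict is None:
        return float("nan")
    pm = verdict.pvalue_matrix
    off = pm[~np.isnan(pm)]
    return float(off.min()) if off.size else float("nan")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    m = int(mask.sum())
    if m == 0:
        return q
    vals = p[mask]
    order = np.argsort(vals)
    adj = vals[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    q[mask] = out
    return q
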
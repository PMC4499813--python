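"""Depth-independent validation of candidate differentially processed loci.

Differences in raw block expression can be sequencing-depth artifacts, so
candidate loci are validated on depth-normalized counts.  A per-sample size
factor s_j is the median of ratios of that sample's block counts to a
pseudo-reference sample (the per-block geometric mean across samples).
Normalized block expressions b_ij / s_j of every pair of samples are compared
with an exact test of independence on the m x 2 contingency table of the m
block expressions; a locus is validated when, for at least one supported
cluster, a strict majority (> 50%) of in-cluster samples is significant
against *every* out-of-cluster sample.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import fisher_exact, random_table

from .cluster import ClusterResult
from .loci import LocusTable

logger = logging.getLogger(__name__)

__all__ = ["SizeFactors", "DPVerdict", "compute_size_factors", "fisher_m_by_2",
           "normalized_block_expression", "validate_dpl", "locus_block_counts"]


@dataclass
class SizeFactors:
    samples: list[str]
    factors: np.ndarray  # s_j > 0, aligned with samples

    def factor(self, sample: str) -> float:
        return float(self.factors[self.samples.index(sample)])


@dataclass
class DPVerdict:
    locus_id: int
    is_dpl: bool
    pvalue_matrix: np.ndarray  # n x n, symmetric, diagonal NaN
    samples: list[str]
    cluster_fractions: list[float]  # per supported cluster: qualifying fraction


def compute_size_factors(k: np.ndarray, samples: list[str]) -> SizeFactors:
    """Median-of-ratios size factors from a block x sample count matrix.

    Rows containing a zero are skipped (their geometric-mean ratio is
    undefined).  s_j = median_i k_ij / (prod_m k_im)^(1/m).
    """
    k = np.asarray(k, dtype=float)
    if k.ndim != 2 or k.shape[1] != len(samples):
        raise ValueError("count matrix shape does not match sample list")
    usable = np.all(k > 0, axis=1)
    if not usable.any():
        raise ValueError(
            "no block has positive counts in every sample; pool more loci or "
            "fall back to library-size normalization"
        )
    ku = k[usable]
    log_geo = np.mean(np.log(ku), axis=1, keepdims=True)
    ratios = ku / np.exp(log_geo)
    s = np.median(ratios, axis=0)
    return SizeFactors(samples=list(samples), factors=s)


def _log_table_weight(a: np.ndarray, rows: np.ndarray) -> float:
    """log prod_i C(rows_i, a_i): the conditional weight of an m x 2 table
    with fixed margins (column margins drop out as a constant)."""
    return float(np.sum(gammaln(rows + 1) - gammaln(a + 1) - gammaln(rows - a + 1)))


def fisher_m_by_2(
    col_a: np.ndarray,
    col_b: np.ndarray,
    seed: int = 0,
    n_mc: int = 10_000,
) -> float:
    """Two-sided exact conditional test of independence on an m x 2 table.

    Inputs are rounded to the nearest non-negative integers (exact tests need
    counts).  For m = 2 the hypergeometric distribution is enumerated exactly;
    for m > 2 the p-value is a Monte Carlo estimate of the exact conditional
    test using Patefield sampling of tables with the observed margins and the
    conservative add-one estimator (1 + #{weight <= observed}) / (1 + n_mc).
    """
    a = np.maximum(0, np.rint(np.asarray(col_a, dtype=float))).astype(np.int64)
    b = np.maximum(0, np.rint(np.asarray(col_b, dtype=float))).astype(np.int64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("fisher_m_by_2 needs two equal-length vectors, m >= 2")
    if a.sum() == 0 or b.sum() == 0:
        logger.warning("all-zero column in contingency table; p = 1")
        return 1.0
    rows = a + b
    keep = rows > 0
    a, b, rows = a[keep], b[keep], rows[keep]
    if len(a) < 2:
        return 1.0
    if len(a) == 2:
        return float(fisher_exact(np.column_stack([a, b]), alternative="two-sided")[1])

    obs_w = _log_table_weight(a, rows)
    rng = np.random.default_rng(seed)
    sampler = random_table(rows, [int(a.sum()), int(b.sum())])
    tables = sampler.rvs(size=n_mc, random_state=rng)  # (n_mc, m, 2)
    aa = tables[:, :, 0]
    w = np.sum(
        gammaln(rows + 1) - gammaln(aa + 1) - gammaln(rows - aa + 1), axis=1
    )
    hits = int(np.sum(w <= obs_w + 1e-9))
    return (1 + hits) / (1 + n_mc)


def locus_block_counts(
    locus: LocusTable, include_dummy_read: bool = True
) -> np.ndarray:
    """Consensus-block x sample raw count matrix at a harmonized locus.

    Non-dummy (consensus) blocks only; ``include_dummy_read`` keeps the single
    harmonization pseudocount in each block (continuity correction for empty
    blocks), while size-factor computation excludes it.
    """
    if not locus.harmonized:
        raise ValueError("locus must be harmonized first")
    rows = []
    n_blocks = len(locus.consensus_coords)
    for bi in range(n_blocks):
        row = []
        for s in locus.samples:
            block = [b for b in locus.groups[s].blocks if not b.is_dummy][bi]
            row.append(block.height if include_dummy_read else block.non_dummy_height)
        rows.append(row)
    return np.asarray(rows, dtype=np.int64)


def normalized_block_expression(
    counts: np.ndarray, size_factors: SizeFactors, samples: list[str]
) -> np.ndarray:
    """b_hat_ij = b_ij / s_j."""
    s = np.array([size_factors.factor(x) for x in samples])
    return np.asarray(counts, dtype=float) / s[np.newaxis, :]


def validate_dpl(
    locus: LocusTable,
    result: ClusterResult,
    size_factors: SizeFactors,
    alpha: float = 0.05,
    replicate_map: dict[str, str] | None = None,
    mode: str = "independent",
    seed: int = 0,
    n_mc: int = 10_000,
) -> DPVerdict:
    """Expression-based validation of one candidate locus.

    Builds the all-vs-all p-value matrix of exact tests on normalized block
    expressions, then for each supported cluster checks the majority rule:
    > 50% of in-cluster samples (cell lines in combined mode, a line counting
    only when both replicates qualify) must be significant against every
    out-of-cluster sample.
    """
    samples = list(locus.samples)
    n = len(samples)
    counts = locus_block_counts(locus, include_dummy_read=True)
    bhat = normalized_block_expression(counts, size_factors, samples)

    pmat = np.full((n, n), np.nan)
    if bhat.shape[0] >= 2:
        for i, j in itertools.combinations(range(n), 2):
            pair_seed = (seed * 1_000_003 + i * 1009 + j) % (2**31)
            p = fisher_m_by_2(bhat[:, i], bhat[:, j], seed=pair_seed, n_mc=n_mc)
            pmat[i, j] = pmat[j, i] = p

    fractions: list[float] = []
    is_dpl = False
    for c in result.significant:
        in_set = sorted(c.eligible_in or c.members)
        out_set = sorted(c.eligible_out or (set(samples) - c.members))
        if not in_set or not out_set:
            continue
        qualifies = {
            s: all(pmat[samples.index(s), samples.index(o)] < alpha for o in out_set)
            for s in in_set
        }
        if mode == "combined":
            if replicate_map is None:
                raise ValueError("combined mode requires a replicate map")
            lines: dict[str, list[str]] = {}
            for s in in_set:
                lines.setdefault(replicate_map[s], []).append(s)
            ok = sum(1 for ss in lines.values() if all(qualifies[s] for s in ss))
            frac = ok / len(lines)
        else:
            frac = sum(qualifies.values()) / len(in_set)
        fractions.append(frac)
        if frac > 0.5:
            is_dpl = True
    return DPVerdict(
        locus_id=locus.locus_id,
        is_dpl=is_dpl,
        pvalue_matrix=pmat,
        samples=samples,
        cluster_fractions=fractions,
    )
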
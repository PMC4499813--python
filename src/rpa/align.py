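"""Pairwise alignment of block groups and read-arrangement entropy.

The aligner scores two read profiles on a [0, 1] scale (0 = dissimilar,
1 = perfectly similar) via a two-tier strategy: per-block similarity first,
then a global order-preserving match/skip alignment over the two
coordinate-ordered block lists.  Read counts are normalized by each profile's
total, so the score is invariant to sequencing depth.  The per-block scorer
is pluggable; any scorer satisfying the [0, 1]/symmetry/self-identity
contract can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .model import Block, BlockGroup

__all__ = [
    "AlignmentScore",
    "block_similarity",
    "align_block_groups",
    "block_group_entropy",
]


@dataclass(frozen=True)
class AlignmentScore:
    """Similarity of two block groups: value in [0, 1] plus the matched
    (index-in-a, index-in-b) block pairs."""

    value: float
    block_pairs: tuple[tuple[int, int], ...]


def _block_distribution(block: Block) -> dict[tuple[int, int], float]:
    """Count-weighted distribution over (start offset, read length).

    Offsets are taken relative to the block's modal read start (the start with
    the largest total count; leftmost on ties) so the distribution is
    translation-invariant.
    """
    weights: dict[int, int] = {}
    for r in block.reads:
        weights[r.start] = weights.get(r.start, 0) + r.count
    peak = max(weights.values())
    modal_start = min(s for s, w in weights.items() if w == peak)  # leftmost on ties
    total = sum(weights.values())
    dist: dict[tuple[int, int], float] = {}
    for r in block.reads:
        key = (r.start - modal_start, r.length)
        dist[key] = dist.get(key, 0.0) + r.count / total
    return dist


def block_similarity(
    x: Block, y: Block, h_x: float, h_y: float, max_shift: int = 3
) -> float:
    """Similarity of two blocks given their profile-normalized heights.

    sigma = (1 - |h_x - h_y|) * max_s sum_u min(p_x(u + s), p_y(u)) where p
    are the blocks' modal-start-anchored (offset, length) read distributions
    and s ranges over small relative shifts (|s| <= ``max_shift``).  The shift
    maximization absorbs the ambiguity of the modal anchor when start weights
    are nearly tied; sigma stays in [0, 1], is symmetric and sigma(x, x) = 1.
    """
    px = _block_distribution(x)
    py = _block_distribution(y)
    overlap = 0.0
    for s in range(-max_shift, max_shift + 1):
        ov = sum(
            min(w, py[(off + s, ln)])
            for (off, ln), w in px.items()
            if (off + s, ln) in py
        )
        overlap = max(overlap, ov)
    return max(0.0, 1.0 - abs(h_x - h_y)) * overlap


SimilarityFn = Callable[[Block, Block, float, float], float]


def align_block_groups(
    a: BlockGroup, b: BlockGroup, similarity: SimilarityFn = block_similarity
) -> AlignmentScore:
    """Two-tier alignment score between two read profiles.

    Tier 1 computes per-block similarities; tier 2 chains them with a global
    match/skip alignment that preserves block order (no crossing matches —
    genomic collinearity) and charges nothing for skips.  The final value is
    2 * (total matched similarity) / (m + n); it reaches 1 exactly when the
    two groups share block structure and normalized read arrangement.
    """
    if not a.blocks or not b.blocks:
        raise ValueError("cannot align an empty block group")
    m, n = len(a.blocks), len(b.blocks)
    tot_a, tot_b = a.total_reads, b.total_reads
    sig = [
        [
            similarity(x, y, x.height / tot_a, y.height / tot_b)
            for y in b.blocks
        ]
        for x in a.blocks
    ]
    # order-preserving maximum-weight matching by dynamic programming
    dp = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            dp[i][j] = max(
                dp[i - 1][j],
                dp[i][j - 1],
                dp[i - 1][j - 1] + sig[i - 1][j - 1],
            )
    # traceback for matched pairs (prefer diagonal on ties, then up)
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 and j > 0:
        if (
            sig[i - 1][j - 1] > 0.0
            and dp[i][j] == dp[i - 1][j - 1] + sig[i - 1][j - 1]
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif dp[i][j] == dp[i - 1][j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    value = 2.0 * dp[m][n] / (m + n)
    return AlignmentScore(value=min(1.0, value), block_pairs=tuple(pairs))


def block_group_entropy(bg: BlockGroup, base: float = 2.0) -> float:
    """Shannon entropy (bits by default) of read start positions.

    Low entropy means the reads are precisely arranged — they start at few
    positions — which is characteristic of deliberate processing.  Dummy
    reads inserted by harmonization are excluded.
    """
    weights: dict[int, int] = {}
    for block in bg.blocks:
        for r in block.reads:
            if r.is_dummy:
                continue
            weights[r.start] = weights.get(r.start, 0) + r.count
    total = sum(weights.values())
    if total == 0:
        raise ValueError("entropy undefined for a group of only dummy reads")
    h = 0.0
    for w in weights.values():
        f = w / total
        h -= f * math.log(f, base)
    return max(0.0, h)
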
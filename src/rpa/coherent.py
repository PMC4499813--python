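"""Coherently processed loci (CPL) and short/precise profile classification.

A locus whose read profiles look alike in every sample — mean pairwise
alignment score >= 0.8 — is called coherently processed.  A profile is
"short and precise" when it consists of a single read block, its read-start
entropy is <= 2 bits and its span is <= 40 nt; this is the signature of
deliberately processed small RNAs such as TSS-associated ~17-nt RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import block_group_entropy
from .cluster import ScoreMatrix
from .model import BlockGroup

__all__ = ["CPCall", "call_cpl", "classify_short_precise"]


@dataclass
class CPCall:
    locus_id: int
    mean_score: float
    is_cpl: bool


def call_cpl(matrix: ScoreMatrix, threshold: float = 0.8, locus_id: int = 0) -> CPCall:
    """Mean of the off-diagonal alignment scores; CPL iff mean >= threshold
    (inclusive)."""
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("CPL call needs at least two samples")
    iu = np.triu_indices(n, k=1)
    mean_score = float(np.mean(matrix.values[iu]))
    return CPCall(locus_id=locus_id, mean_score=mean_score,
                  is_cpl=mean_score >= threshold)


def classify_short_precise(
    bg: BlockGroup,
    entropy_threshold: float = 2.0,
    max_length: int = 40,
) -> bool:
    """True iff the profile has one non-dummy block, entropy <= 2 bits and a
    non-dummy span <= 40 nt.  Dummy blocks are harmonization plumbing and are
    ignored for the block count and length."""
    real = bg.non_dummy_blocks
    if len(real) != 1:
        return False
    if bg.non_dummy_span > max_length:
        return False
    return block_group_entropy(bg) <= entropy_threshold
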
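"""Score the similarity of two read profiles and measure their entropy.

The alignment score S is 1 for identical profiles and falls toward 0 as the
block structure or the within-block read arrangement diverges; it is
invariant to sequencing depth.  Entropy (bits) measures how precisely the
reads' start positions are arranged — low entropy means deliberate
processing.
"""

from rpa import align_block_groups, block_group_entropy
from rpa.model import Block, BlockGroup, MappedRead


def two_arm_profile(sample, major, minor):
    """A two-block profile with `major`/`minor` reads on the 5'/3' arm."""
    blocks = [
        Block.from_reads([MappedRead("chr1", 1000, 1022, "+", major, sample)]),
        Block.from_reads([MappedRead("chr1", 1044, 1066, "+", minor, sample)]),
    ]
    return BlockGroup("chr1", 1000, 1066, "+", blocks=blocks, sample=sample)


liver = two_arm_profile("liver", major=80, minor=20)
liver_deep = two_arm_profile("liver2", major=800, minor=200)  # 10x deeper
brain = two_arm_profile("brain", major=20, minor=80)  # arms switched

print(f"S(liver, liver)      = {align_block_groups(liver, liver).value:.3f}")
print(f"S(liver, 10x deeper) = {align_block_groups(liver, liver_deep).value:.3f}")
print(f"S(liver, brain)      = {align_block_groups(liver, brain).value:.3f}")
print(f"entropy(liver)       = {block_group_entropy(liver):.3f} bits")

# Identical profiles score 1.0 regardless of depth; the arm-switched brain
# profile scores well below 1 — exactly the signal the differential-
# processing pipeline clusters on.  All reads share one start per block, so
# the entropy is 0: a precisely processed profile.
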
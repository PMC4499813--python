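import numpy as np
import pytest

from rpa.model import Block, BlockGroup, MappedRead


def make_read(start, length=20, count=1, chrom="chr1", strand="+", sample="s",
              is_dummy=False):
    return MappedRead(chrom, start, start + length, strand, count, sample, is_dummy)


def make_group(block_specs, chrom="chr1", strand="+", sample="s"):
    """Build a block group from [(start, [(read_start, length, count), ...]), ...]."""
    blocks = []
    for spec in block_specs:
        reads = [
            make_read(rs, ln, c, chrom=chrom, strand=strand, sample=sample)
            for rs, ln, c in spec
        ]
        blocks.append(Block.from_reads(reads))
    g = BlockGroup(chrom, 0, 0, strand, blocks=blocks, sample=sample)
    g.sort_blocks()
    g.recompute_span()
    return g


def random_group(rng, n_blocks=None, origin=None, sample="s"):
    """A random but structurally valid read profile for property tests."""
    n_blocks = n_blocks or int(rng.integers(1, 4))
    origin = origin if origin is not None else int(rng.integers(100, 10_000))
    specs = []
    pos = origin
    for _ in range(n_blocks):
        n_kinds = int(rng.integers(1, 4))
        reads = []
        for _ in range(n_kinds):
            start = pos + int(rng.integers(0, 4))
            length = int(rng.integers(17, 26))
            count = int(rng.integers(1, 50))
            reads.append((start, length, count))
        specs.append(reads)
        pos += int(rng.integers(40, 80))
    return make_group(specs, sample=sample)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
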
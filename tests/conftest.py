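import numpy as np
import pytest

from scafmap.io_formats import FORWARD, REVERSE, AlignmentBlock, SequenceSet


def make_block(
    ref="chr1",
    rs=0,
    re=100,
    query="q1",
    qs=0,
    qe=100,
    orientation=FORWARD,
    identity=100.0,
    block_id=None,
    _counter=[0],
):
    if block_id is None:
        _counter[0] += 1
        block_id = f"b{_counter[0]}"
    return AlignmentBlock(ref, rs, re, query, qs, qe, orientation, identity, block_id)


@pytest.fixture
def mk_block():
    return make_block


def random_blocks(rng, n, chroms=("chr1", "chr2"), chrom_len=50_000, n_queries=8):
    """Random, possibly overlapping alignment blocks for oracle tests."""
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_len - 10))
        length = int(rng.integers(1, min(5000, chrom_len - start)))
        qlen = int(rng.integers(1, 5000))
        out.append(
            AlignmentBlock(
                ref_name=chrom,
                ref_start=start,
                ref_end=start + length,
                query_name=f"q{rng.integers(n_queries)}",
                query_start=0,
                query_end=qlen,
                orientation=FORWARD if rng.random() < 0.8 else REVERSE,
                identity=float(np.round(rng.uniform(80, 100), 3)),
                block_id=f"r{i}",
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chrom_lengths():
    return SequenceSet.from_lengths({"chr1": 50_000, "chr2": 50_000})
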
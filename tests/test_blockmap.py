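"""Block grouping, annotation, colinear chaining, inversions, uncovered
stretches, hotspots and the per-chromosome report."""

import numpy as np
import pytest

from conftest import make_block, random_blocks
from scafmap import blockmap
from scafmap.blockmap import (
    ABUTS_GAP,
    ALIGNMENT_BREAK,
    CHROMOSOME_TERMINUS,
    CONTIG_TERMINUS,
    OVERLAPS_NEIGHBOUR,
)
from scafmap.io_formats import FORWARD, REVERSE, EvalConfig, SequenceSet


# ---------------------------------------------------------------- grouping

def test_group_blocks_partitions_and_counts():
    blocks = [make_block(ref="chr1"), make_block(ref="chr2"), make_block(ref="chr1")]
    grouped = blockmap.group_blocks(blocks)
    assert sorted(grouped) == ["chr1", "chr2"]
    assert sum(len(g) for g in grouped.values()) == 3


def test_group_blocks_sorts_by_ref_start():
    blocks = [
        make_block(rs=500, re=600),
        make_block(rs=100, re=200),
        make_block(rs=300, re=400),
    ]
    grouped = blockmap.group_blocks(blocks)
    assert [b.ref_start for b in grouped["chr1"]] == [100, 300, 500]


def test_group_blocks_random_partition_oracle(rng):
    blocks = random_blocks(rng, 2000, chroms=("chr1", "chr2", "chr3"))
    grouped = blockmap.group_blocks(blocks)
    assert sum(len(g) for g in grouped.values()) == len(blocks)
    for g in grouped.values():
        for a, b in zip(g, g[1:]):
            assert (a.ref_start, a.ref_end) <= (b.ref_start, b.ref_end)


# ---------------------------------------------------------------- annotation

def _annotate(blocks, contig_lengths, chrom_lengths, **cfg):
    grouped = blockmap.group_blocks(blocks)
    return blockmap.annotate_blocks(
        grouped,
        SequenceSet.from_lengths(contig_lengths),
        SequenceSet.from_lengths(chrom_lengths),
        EvalConfig(**cfg) if cfg else None,
    )


def test_full_cover_block_is_chromosome_terminus_both_ends():
    blocks = [make_block(rs=0, re=1000, qs=0, qe=1000)]
    (a,) = _annotate(blocks, {"q1": 1000}, {"chr1": 1000})
    assert a.left_end == CHROMOSOME_TERMINUS and a.right_end == CHROMOSOME_TERMINUS
    assert a.gap_to_next is None and a.ref_len == 1000


def test_large_gap_annotated_abuts_gap():
    blocks = [
        make_block(rs=100, re=10_000, query="q1", qs=0, qe=9_900),
        make_block(rs=16_000, re=20_000, query="q2", qs=100, qe=4_100),
    ]
    anns = _annotate(blocks, {"q1": 10_000, "q2": 5_000}, {"chr1": 30_000})
    assert anns[0].right_end == ABUTS_GAP
    assert anns[0].gap_to_next == 6000
    assert anns[1].left_end == ABUTS_GAP


def test_contig_terminus_respects_orientation():
    # reverse block: its left (low-ref) end corresponds to the contig's 3' end
    blocks = [make_block(rs=100, re=200, qs=400, qe=500, orientation=REVERSE)]
    (a,) = _annotate(blocks, {"q1": 500}, {"chr1": 1000})
    assert a.left_end == CONTIG_TERMINUS  # query_end == contig length
    assert a.right_end == ALIGNMENT_BREAK  # query_start 400 != 0


def test_overlapping_blocks_of_different_contigs_flag_repeats():
    blocks = [
        make_block(rs=100, re=300, query="q1", qs=10, qe=210),
        make_block(rs=200, re=400, query="q2", qs=10, qe=210),
    ]
    anns = _annotate(blocks, {"q1": 1000, "q2": 1000}, {"chr1": 10_000})
    assert all(a.repeat_flag for a in anns)
    assert anns[0].right_end == OVERLAPS_NEIGHBOUR
    assert anns[0].gap_to_next == -100


def test_same_contig_overlap_not_a_repeat():
    blocks = [
        make_block(rs=100, re=300, query="q1", qs=10, qe=210),
        make_block(rs=250, re=400, query="q1", qs=250, qe=400),
    ]
    anns = _annotate(blocks, {"q1": 1000}, {"chr1": 10_000})
    assert not any(a.repeat_flag for a in anns)


def test_repeat_flags_match_pairwise_overlap_oracle(rng):
    blocks = random_blocks(rng, 150, chroms=("chr1",), chrom_len=20_000)
    anns = _annotate(
        blocks,
        {f"q{i}": 5000 for i in range(8)},
        {"chr1": 20_000},
    )
    by_id = {a.block.block_id: a for a in anns}
    for b in blocks:
        expect = any(
            o.query_name != b.query_name
            and o.ref_start < b.ref_end
            and b.ref_start < o.ref_end
            for o in blocks
            if o is not b
        )
        assert by_id[b.block_id].repeat_flag == expect


def test_unknown_sequence_name_errors():
    blocks = [make_block(query="ghost")]
    with pytest.raises(KeyError, match="ghost"):
        _annotate(blocks, {"q1": 100}, {"chr1": 1000})


# ---------------------------------------------------------------- colinear runs

def _runs(blocks, **cfg):
    return blockmap.find_colinear_runs(
        blockmap.group_blocks(blocks), EvalConfig(**cfg) if cfg else None
    )


def test_three_colinear_blocks_chain_into_one_run():
    blocks = [
        make_block(rs=0, re=100, qs=0, qe=100),
        make_block(rs=150, re=250, qs=100, qe=200),
        make_block(rs=330, re=400, qs=200, qe=270),
    ]
    runs = _runs(blocks)
    assert len(runs) == 1
    assert runs[0].ref_span == (0, 400) and runs[0].query_span == (0, 270)
    assert len(runs[0].blocks) == 3


def test_orientation_change_breaks_the_chain():
    blocks = [
        make_block(rs=0, re=100, qs=0, qe=100),
        make_block(rs=150, re=250, qs=100, qe=200, orientation=REVERSE),
        make_block(rs=330, re=400, qs=200, qe=270),
    ]
    assert len(_runs(blocks)) == 3


def test_single_block_is_its_own_run():
    runs = _runs([make_block()])
    assert len(runs) == 1 and len(runs[0].blocks) == 1


def test_gap_beyond_tolerance_breaks_the_chain():
    blocks = [
        make_block(rs=0, re=100, qs=0, qe=100),
        make_block(rs=5000, re=5100, qs=100, qe=200),
    ]
    assert len(_runs(blocks, colinear_gap_tolerance=1000)) == 2
    assert len(_runs(blocks, colinear_gap_tolerance=10_000)) == 1


def test_every_block_in_exactly_one_run(rng):
    blocks = random_blocks(rng, 500)
    runs = _runs(blocks)
    seen = [bid for r in runs for bid in r.blocks]
    assert sorted(seen) == sorted(b.block_id for b in blocks)


# ---------------------------------------------------------------- inversions

def test_flanked_reverse_run_is_confident_inversion():
    blocks = [
        make_block(rs=0, re=100, qs=0, qe=100),
        make_block(rs=100, re=200, qs=100, qe=200, orientation=REVERSE),
        make_block(rs=200, re=300, qs=200, qe=300),
    ]
    inversions = blockmap.detect_inversions(_runs(blocks))
    assert len(inversions) == 1
    inv = inversions[0]
    assert (inv.start, inv.end, inv.flanked) == (100, 200, True)


def test_all_forward_yields_no_inversions():
    blocks = [make_block(rs=i * 100, re=i * 100 + 50, qs=i * 100, qe=i * 100 + 50)
              for i in range(5)]
    assert blockmap.detect_inversions(_runs(blocks)) == []


def test_isolated_reverse_run_is_low_confidence():
    blocks = [make_block(orientation=REVERSE)]
    (inv,) = blockmap.detect_inversions(_runs(blocks))
    assert inv.flanked is False


# ---------------------------------------------------------------- uncovered

def _chrlen(**kw):
    return SequenceSet.from_lengths(kw)


def test_uncovered_stretch_by_hand():
    blocks = [
        make_block(rs=0, re=40_000, qs=0, qe=40_000),
        make_block(rs=46_000, re=100_000, qs=0, qe=54_000, query="q2"),
    ]
    gaps = blockmap.uncovered_stretches(
        blockmap.group_blocks(blocks), _chrlen(chr1=100_000), 5000
    )
    assert [(g.chrom, g.start, g.end, g.length)
            for g in gaps] == [("chr1", 40_000, 46_000, 6000)]


def test_full_cover_has_no_uncovered_stretch():
    blocks = [make_block(rs=0, re=1000, qs=0, qe=1000)]
    assert blockmap.uncovered_stretches(
        blockmap.group_blocks(blocks), _chrlen(chr1=1000), 1
    ) == []


def test_uncovered_complement_tiles_chromosome_at_min_len_one(rng):
    """union(blocks) + uncovered(min_len=1) must tile [0, L) exactly."""
    for _ in range(20):
        blocks = random_blocks(rng, int(rng.integers(1, 40)), chroms=("chr1",),
                               chrom_len=10_000)
        grouped = blockmap.group_blocks(blocks)
        gaps = blockmap.uncovered_stretches(grouped, _chrlen(chr1=10_000), 1)
        mask = np.zeros(10_000, dtype=bool)
        for b in blocks:
            mask[b.ref_start:b.ref_end] = True
        gap_mask = np.zeros(10_000, dtype=bool)
        for g in gaps:
            assert not mask[g.start:g.end].any()
            gap_mask[g.start:g.end] = True
        assert (mask | gap_mask).all()


# ---------------------------------------------------------------- hotspots

def test_hotspot_flags_window_dense_in_boundaries():
    blocks = [
        make_block(rs=200_000 + i * 1000, re=200_000 + i * 1000 + 500,
                   qs=0, qe=500, query=f"q{i}")
        for i in range(30)
    ]
    hs = blockmap.fragmentation_hotspots(
        blockmap.group_blocks(blocks), _chrlen(chr1=3_000_000),
        EvalConfig(hotspot_window=1_000_000, hotspot_min_interruptions=10),
    )
    assert len(hs) == 1 and hs[0].start == 0 and hs[0].end == 1_000_000


def test_single_spanning_block_is_no_hotspot():
    blocks = [make_block(rs=0, re=3_000_000, qs=0, qe=3_000_000)]
    assert blockmap.fragmentation_hotspots(
        blockmap.group_blocks(blocks), _chrlen(chr1=3_000_000)
    ) == []


def test_adjacent_hotspot_windows_merge():
    blocks = [
        make_block(rs=900_000 + i * 20_000, re=900_000 + i * 20_000 + 10_000,
                   qs=0, qe=10_000, query=f"q{i}")
        for i in range(15)
    ]  # boundaries straddle the 1 Mb window edge
    hs = blockmap.fragmentation_hotspots(
        blockmap.group_blocks(blocks), _chrlen(chr1=3_000_000),
        EvalConfig(hotspot_window=100_000, hotspot_min_interruptions=4),
    )
    assert len(hs) == 1
    assert hs[0].start == 900_000 and hs[0].end == 1_200_000


# ---------------------------------------------------------------- report

def test_coverage_uses_interval_union():
    blocks = [
        make_block(rs=0, re=50, qs=0, qe=50),
        make_block(rs=40, re=80, qs=0, qe=40, query="q2"),
    ]
    (r,) = blockmap.chromosome_report(blockmap.group_blocks(blocks), _chrlen(chr1=100))
    assert r.coverage_pct == pytest.approx(80.0)
    assert r.align_start == 1 and r.align_end == 80
    assert r.n_contigs == 2 and r.n_blocks == 2


def test_identity_is_ref_length_weighted():
    blocks = [
        make_block(rs=0, re=100, qs=0, qe=100, identity=100.0),
        make_block(rs=100, re=400, qs=0, qe=300, query="q2", identity=98.0),
    ]
    (r,) = blockmap.chromosome_report(blockmap.group_blocks(blocks), _chrlen(chr1=400))
    assert r.identity_pct == pytest.approx(98.5)


def test_per_chromosome_lx_counts_contigs_toward_chromosome_length():
    blocks = [
        make_block(rs=0, re=60, qs=0, qe=60, query="A"),
        make_block(rs=60, re=90, qs=0, qe=30, query="B"),
        make_block(rs=90, re=95, qs=0, qe=5, query="C"),
    ]
    (r,) = blockmap.chromosome_report(blockmap.group_blocks(blocks), _chrlen(chr1=100))
    assert (r.l50, r.l90) == (1, 2)
    assert not r.shortfall


def test_unreachable_l90_sets_shortfall():
    blocks = [make_block(rs=0, re=30, qs=0, qe=30)]
    (r,) = blockmap.chromosome_report(blockmap.group_blocks(blocks), _chrlen(chr1=100))
    assert r.l90 == 1 and r.shortfall


def test_chromosome_without_blocks_reports_zero_coverage():
    reports = blockmap.chromosome_report({}, _chrlen(chr1=100, chr2=50))
    assert [r.coverage_pct for r in reports] == [0.0, 0.0]
    assert all(r.n_blocks == 0 for r in reports)
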
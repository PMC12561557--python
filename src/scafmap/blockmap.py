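"""Per-chromosome organisation and annotation of contig-to-reference
alignment blocks.

This is the evaluation core of the toolkit: blocks are grouped by the
chromosome they map to, annotated with end categories and neighbour gaps,
chained into colinear runs, and summarised into a per-chromosome report
(alignment span, coverage %, contig count, L50/L90, length-weighted
identity %, block count).  Inversions, uncovered reference stretches and
fragmentation hotspots are derived from the same grouped blocks.

Conventions:

* Per-chromosome L50/L90 use the chromosome length as denominator: the
  minimal number of contigs whose summed aligned length reaches 50%/90% of
  the chromosome.  When 90% is unreachable (e.g. a poorly covered X-like
  chromosome) l90 falls back to the contig count and a shortfall flag is
  set.
* Identity is aggregated as the reference-length-weighted mean of block
  identities.
* The uncovered-stretch length threshold is inclusive (length >= min_len).
* All sorts break ties lexicographically by (name, start) so output order
  is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .io_formats import FORWARD, REVERSE, AlignmentBlock, EvalConfig, SequenceSet

# end-annotation kinds, in precedence order
CHROMOSOME_TERMINUS = "chromosome_terminus"
CONTIG_TERMINUS = "contig_terminus"
OVERLAPS_NEIGHBOUR = "overlaps_neighbour"
ABUTS_GAP = "abuts_gap"
ALIGNMENT_BREAK = "alignment_break"


@dataclass
class BlockAnnotation:
    block: AlignmentBlock
    ref_len: int
    query_len: int
    left_end: str
    right_end: str
    gap_to_next: Optional[int]  # None for the last block on a chromosome
    run_id: Optional[str]
    repeat_flag: bool


@dataclass
class ColinearRun:
    """A maximal chain of same-query, same-orientation blocks advancing
    monotonically along the reference."""

    run_id: str
    chrom: str
    query_name: str
    orientation: str
    blocks: list[str]  # block_ids in chain order
    ref_span: tuple[int, int]
    query_span: tuple[int, int]


@dataclass
class GapInterval:
    chrom: str
    start: int
    end: int
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        self.length = self.end - self.start


@dataclass
class InversionSegment:
    chrom: str
    start: int
    end: int
    query_name: str
    flanked: bool  # True when same-query forward runs flank it in reference order

    @property
    def name(self) -> str:  # BED name column
        conf = "flanked" if self.flanked else "isolated"
        return f"{self.query_name};{conf}"


@dataclass
class ChromosomeReport:
    chrom: str
    align_start: int  # 1-based inclusive; 0 when no blocks
    align_end: int
    coverage_pct: float
    n_contigs: int
    l90: int
    l50: int
    identity_pct: float
    n_blocks: int
    shortfall: bool = False


GroupedBlocks = dict[str, list[AlignmentBlock]]


def group_blocks(blocks: list[AlignmentBlock]) -> GroupedBlocks:
    """Partition blocks by chromosome; within each group sort stably by
    (ref_start, ref_end)."""
    grouped: GroupedBlocks = {}
    for b in blocks:
        grouped.setdefault(b.ref_name, []).append(b)
    for chrom in grouped:
        grouped[chrom].sort(key=lambda b: (b.ref_start, b.ref_end))
    return dict(sorted(grouped.items()))


def _merged_intervals(blocks: list[AlignmentBlock]) -> list[tuple[int, int]]:
    """Union of block reference intervals as a sorted list of disjoint
    half-open intervals (blocks must be sorted by ref_start)."""
    merged: list[tuple[int, int]] = []
    for b in blocks:
        if merged and b.ref_start <= merged[-1][1]:
            if b.ref_end > merged[-1][1]:
                merged[-1] = (merged[-1][0], b.ref_end)
        else:
            merged.append((b.ref_start, b.ref_end))
    return merged


def annotate_blocks(
    grouped: GroupedBlocks,
    contig_lengths: SequenceSet,
    chrom_lengths: SequenceSet,
    config: EvalConfig | None = None,
    runs: list[ColinearRun] | None = None,
) -> list[BlockAnnotation]:
    """Annotate every block with end categories, neighbour gap and repeat flag.

    End categories are assigned by precedence: chromosome_terminus (block
    touches position 0 or the chromosome end), contig_terminus (the
    corresponding query coordinate touches the contig end, respecting
    orientation), overlaps_neighbour (negative gap on that side), abuts_gap
    (neighbouring reference gap >= min_uncovered_stretch), otherwise
    alignment_break.
    """
    config = config or EvalConfig()
    run_of_block: dict[str, str] = {}
    if runs is not None:
        for run in runs:
            for bid in run.blocks:
                run_of_block[bid] = run.run_id

    annotations: list[BlockAnnotation] = []
    for chrom, blocks in grouped.items():
        chrom_len = chrom_lengths.length(chrom)
        tree = IntervalTree()
        for i, b in enumerate(blocks):
            tree.addi(b.ref_start, b.ref_end, b.query_name)
        for i, b in enumerate(blocks):
            qlen = contig_lengths.length(b.query_name)
            prev_end = blocks[i - 1].ref_end if i > 0 else 0
            next_start = blocks[i + 1].ref_start if i + 1 < len(blocks) else chrom_len
            left_gap = b.ref_start - prev_end
            right_gap = next_start - b.ref_end
            gap_to_next = (
                blocks[i + 1].ref_start - b.ref_end if i + 1 < len(blocks) else None
            )

            if b.orientation == FORWARD:
                left_touches_contig = b.query_start == 0
                right_touches_contig = b.query_end == qlen
            else:
                left_touches_contig = b.query_end == qlen
                right_touches_contig = b.query_start == 0

            def classify(touches_chrom: bool, touches_contig: bool, gap: int) -> str:
                if touches_chrom:
                    return CHROMOSOME_TERMINUS
                if touches_contig:
                    return CONTIG_TERMINUS
                if gap < 0:
                    return OVERLAPS_NEIGHBOUR
                if gap >= config.min_uncovered_stretch:
                    return ABUTS_GAP
                return ALIGNMENT_BREAK

            left_end = classify(b.ref_start == 0, left_touches_contig, left_gap)
            right_end = classify(b.ref_end == chrom_len, right_touches_contig, right_gap)
            repeat = any(
                iv.data != b.query_name for iv in tree.overlap(b.ref_start, b.ref_end)
            )
            annotations.append(
                BlockAnnotation(
                    block=b,
                    ref_len=b.ref_len,
                    query_len=b.query_len,
                    left_end=left_end,
                    right_end=right_end,
                    gap_to_next=gap_to_next,
                    run_id=run_of_block.get(b.block_id),
                    repeat_flag=repeat,
                )
            )
    return annotations


def find_colinear_runs(grouped: GroupedBlocks, config: EvalConfig | None = None) -> list[ColinearRun]:
    """Chain blocks greedily, left to right per chromosome.

    The next block extends the current run iff it has the same query and
    orientation, its reference start does not precede the current end
    (non-negative progression), the reference gap is within
    colinear_gap_tolerance, and its query coordinates progress in the
    direction the orientation implies.  Every block lands in exactly one run.
    """
    config = config or EvalConfig()
    runs: list[ColinearRun] = []
    for chrom, blocks in grouped.items():
        current: list[AlignmentBlock] = []

        def flush() -> None:
            if not current:
                return
            ref_span = (current[0].ref_start, current[-1].ref_end)
            qmin = min(b.query_start for b in current)
            qmax = max(b.query_end for b in current)
            runs.append(
                ColinearRun(
                    run_id=f"{chrom}:run{len(runs)}",
                    chrom=chrom,
                    query_name=current[0].query_name,
                    orientation=current[0].orientation,
                    blocks=[b.block_id for b in current],
                    ref_span=ref_span,
                    query_span=(qmin, qmax),
                )
            )

        for b in blocks:
            if current:
                last = current[-1]
                gap = b.ref_start - last.ref_end
                same = b.query_name == last.query_name and b.orientation == last.orientation
                ref_ok = 0 <= gap <= config.colinear_gap_tolerance
                if b.orientation == FORWARD:
                    query_ok = b.query_start >= last.query_end
                else:
                    query_ok = b.query_end <= last.query_start
                if same and ref_ok and query_ok:
                    current.append(b)
                    continue
                flush()
                current = []
            current = [b]
        flush()
    return runs


def detect_inversions(runs: list[ColinearRun]) -> list[InversionSegment]:
    """Report reverse-orientation runs as inversion segments.

    A reverse run whose query also has forward runs both before and after it
    along the reference of the same chromosome is a flanked (confident)
    inversion; a reverse run without that same-query forward context is
    reported with flanked=False (lower confidence).
    """
    by_chrom: dict[str, list[ColinearRun]] = {}
    for run in runs:
        by_chrom.setdefault(run.chrom, []).append(run)
    out: list[InversionSegment] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda r: (r.ref_span[0], r.ref_span[1]))
        for i, run in enumerate(ordered):
            if run.orientation != REVERSE:
                continue
            fwd_before = any(
                r.query_name == run.query_name and r.orientation == FORWARD
                for r in ordered[:i]
            )
            fwd_after = any(
                r.query_name == run.query_name and r.orientation == FORWARD
                for r in ordered[i + 1 :]
            )
            out.append(
                InversionSegment(
                    chrom=chrom,
                    start=run.ref_span[0],
                    end=run.ref_span[1],
                    query_name=run.query_name,
                    flanked=fwd_before and fwd_after,
                )
            )
    return out


def uncovered_stretches(
    grouped: GroupedBlocks,
    chrom_lengths: SequenceSet,
    min_len: int,
) -> list[GapInterval]:
    """Complement of the union of block intervals within [0, chrom_len),
    keeping stretches of length >= min_len (inclusive threshold).

    Chromosomes present in chrom_lengths but without blocks yield one
    stretch spanning the whole chromosome (if long enough).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out: list[GapInterval] = []
    for chrom in chrom_lengths:
        chrom_len = chrom_lengths.length(chrom)
        blocks = grouped.get(chrom, [])
        pos = 0
        for start, end in _merged_intervals(blocks):
            if start - pos >= min_len:
                out.append(GapInterval(chrom, pos, start))
            pos = max(pos, end)
        if chrom_len - pos >= min_len:
            out.append(GapInterval(chrom, pos, chrom_len))
    return out


def fragmentation_hotspots(
    grouped: GroupedBlocks,
    chrom_lengths: SequenceSet,
    config: EvalConfig | None = None,
) -> list[GapInterval]:
    """Flag windows dense in block boundaries.

    The chromosome is scanned in non-overlapping windows of hotspot_window
    bases; a window with >= hotspot_min_interruptions block boundaries
    (starts + ends) is a hotspot, and adjacent hotspot windows merge into one
    reported interval.
    """
    config = config or EvalConfig()
    w = config.hotspot_window
    out: list[GapInterval] = []
    for chrom in sorted(grouped):
        chrom_len = chrom_lengths.length(chrom)
        boundaries = sorted(
            p for b in grouped[chrom] for p in (b.ref_start, b.ref_end)
        )
        n_windows = (chrom_len + w - 1) // w
        hot: list[int] = []
        bi = 0
        for k in range(n_windows):
            lo, hi = k * w, min((k + 1) * w, chrom_len)
            count = 0
            while bi < len(boundaries) and boundaries[bi] < hi:
                if boundaries[bi] >= lo:
                    count += 1
                bi += 1
            if count >= config.hotspot_min_interruptions:
                hot.append(k)
        run_start = None
        prev = None
        for k in hot + [None]:
            if k is not None and prev is not None and k == prev + 1:
                prev = k
                continue
            if run_start is not None:
                out.append(
                    GapInterval(chrom, run_start * w, min((prev + 1) * w, chrom_len))
                )
            run_start, prev = k, k
    return out


def _per_chrom_lx(aligned_per_contig: dict[str, int], chrom_len: int, x: int) -> tuple[int, bool]:
    """Minimal number of contigs whose summed aligned length reaches x% of
    the chromosome; (n_contigs, shortfall=True) when unreachable."""
    sums = sorted(aligned_per_contig.values(), reverse=True)
    target = x * chrom_len  # compare 100*cum >= x*chrom_len in exact ints
    cum = 0
    for rank, s in enumerate(sums, 1):
        cum += s
        if 100 * cum >= target:
            return rank, False
    return len(sums), True


def chromosome_report(
    grouped: GroupedBlocks,
    chrom_lengths: SequenceSet,
) -> list[ChromosomeReport]:
    """One report row per reference chromosome (coverage, contigs, L50/L90,
    identity, block count).  Chromosomes with no blocks get coverage 0."""
    reports: list[ChromosomeReport] = []
    for chrom in chrom_lengths:
        chrom_len = chrom_lengths.length(chrom)
        blocks = grouped.get(chrom, [])
        if not blocks:
            reports.append(
                ChromosomeReport(
                    chrom=chrom,
                    align_start=0,
                    align_end=0,
                    coverage_pct=0.0,
                    n_contigs=0,
                    l90=0,
                    l50=0,
                    identity_pct=0.0,
                    n_blocks=0,
                    shortfall=True,
                )
            )
            continue
        covered = sum(e - s for s, e in _merged_intervals(blocks))
        total_ref_len = sum(b.ref_len for b in blocks)
        identity = sum(b.identity * b.ref_len for b in blocks) / total_ref_len
        aligned_per_contig: dict[str, int] = {}
        for b in blocks:
            aligned_per_contig[b.query_name] = (
                aligned_per_contig.get(b.query_name, 0) + b.ref_len
            )
        l50, short50 = _per_chrom_lx(aligned_per_contig, chrom_len, 50)
        l90, short90 = _per_chrom_lx(aligned_per_contig, chrom_len, 90)
        reports.append(
            ChromosomeReport(
                chrom=chrom,
                align_start=min(b.ref_start for b in blocks) + 1,
                align_end=max(b.ref_end for b in blocks),
                coverage_pct=100.0 * covered / chrom_len,
                n_contigs=len(aligned_per_contig),
                l90=l90,
                l50=l50,
                identity_pct=identity,
                n_blocks=len(blocks),
                shortfall=short50 or short90,
            )
        )
    return reports
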
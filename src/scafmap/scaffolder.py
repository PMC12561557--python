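"""Reference-guided scaffolding: assign, order and orient contigs per
chromosome and infer inter-contig gap sizes from the reference coordinates
of their alignment anchors.

The model is one output scaffold per reference chromosome.  Contigs are
never broken: each contig is assigned to the chromosome carrying the
majority of its aligned length (argmax over summed block reference
lengths), oriented by an aligned-length-weighted majority vote over its
blocks, anchored at [min ref_start, max ref_end) of its majority-orientation
blocks, and sorted by anchor midpoint.  The gap after a contig is the
distance between its anchor end and the next anchor start; abutting or
overlapping anchors get a fixed min_gap_size spacer instead (contigs are
not trimmed or merged), while positive inferred gaps are kept exactly even
when smaller than min_gap_size.

Everything here is deterministic: identical blocks and config reproduce
identical scaffolds bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .io_formats import FORWARD, REVERSE, AlignmentBlock, EvalConfig, SequenceSet


@dataclass
class Placement:
    """One contig placed on one chromosome."""

    query_name: str
    chrom: str
    order_index: int
    orientation: str
    anchor_start: int  # 0-based half-open reference extent of the contig's blocks
    anchor_end: int
    assign_fraction: float  # fraction of the contig's aligned length on this chromosome
    gap_after: Optional[int] = None  # N bases inserted after; None for the last contig


@dataclass
class ScaffoldSet:
    placements: dict[str, list[Placement]]  # chrom -> ordered placements
    unplaced: list[str]
    provenance: dict = field(default_factory=dict)


def assign_contigs(
    blocks: list[AlignmentBlock],
    contig_lengths: SequenceSet,
    config: EvalConfig | None = None,
) -> tuple[dict[str, tuple[str, float]], list[str]]:
    """Assign each contig to the chromosome holding most of its aligned length.

    Returns (assignments, unplaced): assignments maps query -> (chrom,
    assign_fraction).  A contig goes unplaced when its best-chromosome
    fraction is below min_assign_fraction, its total aligned length is below
    min_contig, or it has no blocks at all.  Argmax ties break by
    chromosome name order.
    """
    if not blocks:
        raise ValueError("no alignment blocks")
    config = config or EvalConfig()
    aligned: dict[str, dict[str, int]] = {}
    for b in blocks:
        per_chrom = aligned.setdefault(b.query_name, {})
        per_chrom[b.ref_name] = per_chrom.get(b.ref_name, 0) + b.ref_len

    assignments: dict[str, tuple[str, float]] = {}
    unplaced: list[str] = []
    for query in contig_lengths:
        per_chrom = aligned.get(query)
        if not per_chrom:
            unplaced.append(query)
            continue
        total = sum(per_chrom.values())
        best_chrom = max(sorted(per_chrom), key=lambda c: per_chrom[c])
        fraction = per_chrom[best_chrom] / total
        if fraction < config.min_assign_fraction or total < config.min_contig:
            unplaced.append(query)
        else:
            assignments[query] = (best_chrom, fraction)
    return assignments, unplaced


def order_and_orient(
    assignments: dict[str, tuple[str, float]],
    blocks: list[AlignmentBlock],
) -> dict[str, list[Placement]]:
    """Anchor, orient and order assigned contigs along each chromosome.

    Orientation is the aligned-length-weighted majority over the contig's
    blocks on its assigned chromosome (ties go forward); the anchor is the
    reference extent of its majority-orientation blocks; contigs sort by
    anchor midpoint, ties by name.
    """
    by_query: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_query.setdefault(b.query_name, []).append(b)

    pending: dict[str, list[tuple[float, str, Placement]]] = {}
    for query, (chrom, fraction) in assignments.items():
        qblocks = [b for b in by_query.get(query, []) if b.ref_name == chrom]
        fwd_len = sum(b.ref_len for b in qblocks if b.orientation == FORWARD)
        rev_len = sum(b.ref_len for b in qblocks if b.orientation == REVERSE)
        orientation = REVERSE if rev_len > fwd_len else FORWARD
        anchored = [b for b in qblocks if b.orientation == orientation]
        anchor_start = min(b.ref_start for b in anchored)
        anchor_end = max(b.ref_end for b in anchored)
        placement = Placement(
            query_name=query,
            chrom=chrom,
            order_index=0,
            orientation=orientation,
            anchor_start=anchor_start,
            anchor_end=anchor_end,
            assign_fraction=fraction,
        )
        midpoint = (anchor_start + anchor_end) / 2
        pending.setdefault(chrom, []).append((midpoint, query, placement))

    placements: dict[str, list[Placement]] = {}
    for chrom in sorted(pending):
        ordered = sorted(pending[chrom], key=lambda t: (t[0], t[1]))
        row = []
        for i, (_mid, _q, pl) in enumerate(ordered):
            pl.order_index = i
            row.append(pl)
        placements[chrom] = row
    return placements


def infer_gaps(
    placements: dict[str, list[Placement]],
    config: EvalConfig | None = None,
) -> dict[str, list[Placement]]:
    """Set gap_after from consecutive anchor distances.

    A positive anchor distance is used verbatim (even below min_gap_size);
    abutting or overlapping anchors get the fixed min_gap_size spacer.  The
    last contig on a chromosome gets no gap.
    """
    config = config or EvalConfig()
    for chrom, row in placements.items():
        for i, pl in enumerate(row):
            if i + 1 < len(row):
                gap = row[i + 1].anchor_start - pl.anchor_end
                pl.gap_after = gap if gap > 0 else config.min_gap_size
            else:
                pl.gap_after = None
    return placements


def build_scaffolds(
    placements: dict[str, list[Placement]],
    contigs: SequenceSet,
    unplaced: list[str] | None = None,
    config: EvalConfig | None = None,
) -> tuple[SequenceSet, ScaffoldSet]:
    """Concatenate oriented contigs with N-gaps into one scaffold per
    chromosome; unplaced contigs pass through unchanged under their own
    names."""
    config = config or EvalConfig()
    unplaced = list(unplaced or [])
    scaffolds = SequenceSet()
    for chrom in sorted(placements):
        parts: list[str] = []
        for pl in placements[chrom]:
            if pl.query_name not in contigs or not contigs.has_sequence(pl.query_name):
                raise ValueError(f"missing contig sequence for {pl.query_name!r}")
            seq = contigs.sequence(pl.query_name)
            if pl.orientation == REVERSE:
                seq = str(Seq(seq).reverse_complement())
            parts.append(seq)
            if pl.gap_after is not None:
                parts.append("N" * pl.gap_after)
        scaffolds.add(f"{chrom}_scaffold", sequence="".join(parts))
    for name in unplaced:
        if contigs.has_sequence(name):
            scaffolds.add(name, sequence=contigs.sequence(name))
        else:
            scaffolds.add(name, length=contigs.length(name))
    scaffold_set = ScaffoldSet(
        placements=placements,
        unplaced=unplaced,
        provenance=config.to_dict(),
    )
    return scaffolds, scaffold_set


def scaffold(
    blocks: list[AlignmentBlock],
    contigs: SequenceSet,
    config: EvalConfig | None = None,
) -> tuple[SequenceSet, ScaffoldSet]:
    """Full pipeline: assign -> order/orient -> infer gaps -> build."""
    config = config or EvalConfig()
    assignments, unplaced = assign_contigs(blocks, contigs, config)
    placements = order_and_orient(assignments, blocks)
    infer_gaps(placements, config)
    return build_scaffolds(placements, contigs, unplaced, config)


def write_placement_tsv(scaffold_set: ScaffoldSet, path) -> None:
    """Placement table: one row per placed contig, 1-based anchor coords."""
    with open(path, "w") as fh:
        fh.write(
            "query_name\tchrom\torder_index\torientation\t"
            "anchor_start\tanchor_end\tassign_fraction\tgap_after\n"
        )
        for chrom in sorted(scaffold_set.placements):
            for pl in scaffold_set.placements[chrom]:
                gap = "" if pl.gap_after is None else str(pl.gap_after)
                fh.write(
                    f"{pl.query_name}\t{pl.chrom}\t{pl.order_index}\t{pl.orientation}\t"
                    f"{pl.anchor_start + 1}\t{pl.anchor_end}\t{pl.assign_fraction:.4f}\t{gap}\n"
                )
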
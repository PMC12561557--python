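"""Rendering and tabular reporting.

Two per-chromosome views are drawn.  The stacked map gives each contig its
own horizontal level and draws one rectangle per alignment block at its
reference coordinates, with a vertical tick at every block boundary.  The
dotplot draws each block as a line segment from (ref_start, query_start)
to (ref_end, query_end) with contigs stacked cumulatively on the vertical
axis — forward blocks slope up, reverse blocks slope down — tagged with a
circle at the start and a triangle at the stop.

SVG is the canonical output: every data element carries a gid
(block-rect-*, boundary-*, block-seg-*, start-circle-*, stop-triangle-*)
so files are machine-checkable; PNG is a rasterised convenience.
Percentages in the tabular reports are printed with one decimal (Python's
default float formatting, i.e. round-half-even on the binary value).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .asm_stats import AssemblyStats
from .blockmap import BlockAnnotation, ChromosomeReport
from .io_formats import FORWARD, AlignmentBlock, write_bed

REPORT_COLUMNS = (
    "Chromosome",
    "Start",
    "End",
    "Coverage",
    "n Contigs",
    "L90",
    "L50",
    "Identity",
    "n Blocks",
)

_PALETTE = plt.get_cmap("tab20").colors


def _contig_order(blocks: list[AlignmentBlock]) -> list[str]:
    """Contigs ordered by their leftmost reference position."""
    leftmost: dict[str, int] = {}
    for b in blocks:
        if b.query_name not in leftmost or b.ref_start < leftmost[b.query_name]:
            leftmost[b.query_name] = b.ref_start
    return sorted(leftmost, key=lambda q: (leftmost[q], q))


def render_stacked_map(
    blocks: list[AlignmentBlock],
    path: str | Path,
    contig_order: list[str] | None = None,
    title: str | None = None,
) -> None:
    """One level per contig, one rectangle per block, ticks at boundaries."""
    if not blocks:
        raise ValueError("nothing to draw")
    order = contig_order or _contig_order(blocks)
    level = {q: i for i, q in enumerate(order)}

    fig, ax = plt.subplots(figsize=(10, max(2, 0.28 * len(order) + 1)))
    for i, b in enumerate(blocks):
        y = level[b.query_name]
        colour = _PALETTE[level[b.query_name] % len(_PALETTE)]
        rect = Rectangle((b.ref_start, y - 0.35), b.ref_len, 0.7,
                         facecolor=colour, edgecolor="none")
        rect.set_gid(f"block-rect-{i}")
        ax.add_patch(rect)
        for side, x in (("s", b.ref_start), ("e", b.ref_end)):
            (line,) = ax.plot([x, x], [y - 0.45, y + 0.45], color="black", lw=0.6)
            line.set_gid(f"boundary-{i}{side}")
    ax.set_xlim(0, max(b.ref_end for b in blocks) * 1.02)
    ax.set_ylim(-1, len(order))
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=6)
    ax.set_xlabel("reference position (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def render_dotplot(
    blocks: list[AlignmentBlock],
    path: str | Path,
    title: str | None = None,
) -> None:
    """Segment per block with start circle and stop triangle; contigs
    stacked cumulatively on the y axis; reverse blocks slope down."""
    if not blocks:
        raise ValueError("nothing to draw")
    order = _contig_order(blocks)
    span = {q: max(b.query_end for b in blocks if b.query_name == q) for q in order}
    offset: dict[str, int] = {}
    cum = 0
    for q in order:
        offset[q] = cum
        cum += span[q]

    fig, ax = plt.subplots(figsize=(8, 8))
    for i, b in enumerate(blocks):
        off = offset[b.query_name]
        if b.orientation == FORWARD:
            y0, y1 = off + b.query_start, off + b.query_end
        else:
            y0, y1 = off + b.query_end, off + b.query_start
        colour = _PALETTE[order.index(b.query_name) % len(_PALETTE)]
        (seg,) = ax.plot([b.ref_start, b.ref_end], [y0, y1], color=colour, lw=1.2)
        seg.set_gid(f"block-seg-{i}")
        (circ,) = ax.plot([b.ref_start], [y0], marker="o", ms=3, color=colour)
        circ.set_gid(f"start-circle-{i}")
        (tri,) = ax.plot([b.ref_end], [y1], marker="^", ms=3, color=colour)
        tri.set_gid(f"stop-triangle-{i}")
    ax.set_xlabel("reference position (bp)")
    ax.set_ylabel("stacked contig position (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def write_reports(
    stats: AssemblyStats | None,
    reports: list[ChromosomeReport],
    annotations: list[BlockAnnotation],
    prefix: str | Path,
    gaps=None,
    hotspots=None,
    inversions=None,
) -> list[Path]:
    """Write the tabular outputs under the given path prefix.

    Produces <prefix>_assembly.tsv (one row of whole-assembly statistics),
    <prefix>_chromosomes.tsv (per-chromosome table), <prefix>_blocks.tsv
    (block annotations) and, when given, BED files of uncovered stretches,
    hotspots and inversions.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if stats is not None:
        p = prefix.parent / f"{prefix.name}_assembly.tsv"
        row = stats.to_row()
        with open(p, "w") as fh:
            fh.write("\t".join(row) + "\n")
            fh.write("\t".join(str(v) for v in row.values()) + "\n")
        written.append(p)

    p = prefix.parent / f"{prefix.name}_chromosomes.tsv"
    with open(p, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in reports:
            fh.write(
                f"{r.chrom}\t{r.align_start}\t{r.align_end}\t{r.coverage_pct:.1f}\t"
                f"{r.n_contigs}\t{r.l90}\t{r.l50}\t{r.identity_pct:.1f}\t{r.n_blocks}\n"
            )
    written.append(p)

    p = prefix.parent / f"{prefix.name}_blocks.tsv"
    with open(p, "w") as fh:
        fh.write(
            "block_id\tref_name\tref_start\tref_end\tquery_name\tquery_start\t"
            "query_end\torientation\tidentity\tleft_end\tright_end\t"
            "gap_to_next\trun_id\trepeat\n"
        )
        for a in annotations:
            b = a.block
            gap = "" if a.gap_to_next is None else str(a.gap_to_next)
            fh.write(
                f"{b.block_id}\t{b.ref_name}\t{b.ref_start + 1}\t{b.ref_end}\t"
                f"{b.query_name}\t{b.query_start + 1}\t{b.query_end}\t{b.orientation}\t"
                f"{b.identity:.1f}\t{a.left_end}\t{a.right_end}\t{gap}\t"
                f"{a.run_id or ''}\t{int(a.repeat_flag)}\n"
            )
    written.append(p)

    for name, items in (("uncovered", gaps), ("hotspots", hotspots), ("inversions", inversions)):
        if items is not None:
            p = prefix.parent / f"{prefix.name}_{name}.bed"
            write_bed(items, p)
            written.append(p)
    return written
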
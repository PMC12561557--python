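"""Synthetic fragmented-genome simulator with exact ground truth.

The generator emulates the geometry a reference-guided evaluation sees when
a long-read assembly of a mammalian-like genome is mapped back onto its
reference: chromosomes covered almost end to end by long colinear contigs,
rare uncovered stretches, occasional inversions, and one repeat-rich
"centromere" region that shatters into many short multi-mapping fragments.
It builds a random reference, cuts it into contigs with controlled losses,
and emits the exact alignment blocks each contig would produce — so every
downstream stage (annotation, reports, scaffolding) is testable offline
with no aligner and no sequencing data.

Randomness is drawn from numpy Generator streams derived from the single
config seed: stream (seed, 0) builds the reference, stream (seed, 1) does
the fragmentation, and identity noise takes its own caller-supplied seed.
Identical configs are bit-reproducible.

Two inversion styles are supported.  ``inversion_mode="contig"`` flips whole
fragments (the contig is reverse-complemented; its single block is reverse).
``inversion_mode="internal"`` reverse-complements an interior slice of the
fragment, producing a forward/reverse/forward block triplet for that contig
— the pattern a true inversion inside a long contig shows in a dotplot, and
the pattern the flanked-inversion detector is designed to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Seq import Seq

from .blockmap import GapInterval
from .io_formats import (
    FORWARD,
    REVERSE,
    AlignmentBlock,
    SequenceSet,
    write_bed,
    write_block_tsv,
    write_fasta,
)

#: fragments are never cut closer than this to another cut or a segment edge
MIN_FRAGMENT = 2000

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CentromereSpec:
    """A tandem repeat array spliced into one chromosome and shattered into
    micro-fragments at assembly time."""

    chrom: str = "chr1"
    position: int = 450_000
    array_length: int = 50_000
    repeat_unit_length: int = 171  # alphoid-like unit; cosmetic
    shatter_count: int = 50


@dataclass
class SimConfig:
    """Study conditions for one simulated genome.

    Defaults describe the toy scale used throughout the test-suite: three
    chromosomes of 2 / 1 / 0.5 Mb, ~30 fragments each, one 50 kb shattered
    centromere-like array on chr1, no drops, no inversions, no identity
    noise.  Scenario knobs (drops, inversions, noise, break losses) default
    off so the baseline genome reconstructs its reference exactly.
    """

    chrom_lengths: list[int] = field(default_factory=lambda: [2_000_000, 1_000_000, 500_000])
    n_fragments_per_chrom: int = 30
    dropped_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    inversion_rate: float = 0.0
    inversion_mode: str = "contig"  # "contig" flips whole fragments; "internal" flips a slice
    break_loss: tuple[int, int] = (0, 0)  # bases lost at each cut, uniform inclusive range
    centromere: Optional[CentromereSpec] = field(default_factory=CentromereSpec)
    identity_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chrom_lengths must be positive")
        if not 0.0 <= self.inversion_rate <= 1.0:
            raise ValueError("inversion_rate must be in [0, 1]")
        if not 0.0 <= self.identity_noise < 1.0:
            raise ValueError("identity_noise must be in [0, 1)")
        if self.inversion_mode not in ("contig", "internal"):
            raise ValueError(f"unknown inversion_mode {self.inversion_mode!r}")
        lo, hi = self.break_loss
        if lo < 0 or hi < lo:
            raise ValueError("break_loss must be a non-negative (lo, hi) range")
        if hi > 1000:
            raise ValueError("break_loss upper bound must stay below the minimum fragment size")
        if self.n_fragments_per_chrom < 1:
            raise ValueError("n_fragments_per_chrom must be >= 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


@dataclass
class SimTruth:
    """Everything the simulator knows that an evaluator should recover."""

    true_blocks: list[AlignmentBlock]
    true_order: dict[str, list[tuple[str, str]]]  # chrom -> [(contig, orientation)]
    true_gaps: dict[str, list[int]]  # chrom -> inter-fragment reference distances
    true_inversions: list[GapInterval]
    true_dropped: list[GapInterval]
    true_losses: list[GapInterval]  # small per-cut losses (subset of dropped bases)
    centromere_interval: Optional[GapInterval] = None


def simulate_reference(config: SimConfig) -> SequenceSet:
    """Uniform-random chromosomes, with the centromere array spliced in."""
    rng = np.random.default_rng([config.seed, 0])
    ref = SequenceSet()
    cent = config.centromere
    for name, length in zip(config.chrom_names(), config.chrom_lengths):
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        if cent is not None and cent.chrom == name:
            if cent.position + cent.array_length > length:
                raise ValueError(
                    f"centromere interval exceeds {name} "
                    f"({cent.position}+{cent.array_length} > {length})"
                )
            unit = _BASES[rng.integers(0, 4, size=cent.repeat_unit_length)].tobytes().decode()
            copies = -(-cent.array_length // len(unit))
            array = (unit * copies)[: cent.array_length]
            seq = seq[: cent.position] + array + seq[cent.position + cent.array_length :]
        ref.add(name, sequence=seq)
    return ref


def _kept_segments(
    length: int,
    drops: list[tuple[int, int]],
    cent: Optional[tuple[int, int]],
) -> list[tuple[int, int, str]]:
    """Split [0, length) into ('normal'|'cent') segments around the drops."""
    events = [(s, e, "drop") for s, e in drops]
    if cent is not None:
        events.append((cent[0], cent[1], "cent"))
    events.sort()
    prev_end = 0
    segments: list[tuple[int, int, str]] = []
    for s, e, kind in events:
        if s < prev_end:
            raise ValueError("dropped/centromere intervals overlapping")
        if e > length:
            raise ValueError("interval exceeds chromosome length")
        if s > prev_end:
            segments.append((prev_end, s, "normal"))
        if kind == "cent":
            segments.append((s, e, "cent"))
        prev_end = e
    if prev_end < length:
        segments.append((prev_end, length, "normal"))
    return segments


def fragment_genome(reference: SequenceSet, config: SimConfig) -> tuple[SequenceSet, SimTruth]:
    """Cut the reference into contigs and emit their exact alignment blocks.

    Per chromosome: dropped intervals are excised and recorded; the
    remaining sequence is cut at ~n_fragments_per_chrom random positions
    (each cut at least MIN_FRAGMENT from its neighbours); every cut loses a
    uniform break_loss stretch from the start of the following fragment; the
    centromere array, if present, is instead re-cut into shatter_count
    equal micro-fragments.  Fragments become contigs named
    ``<chrom>_f<k>`` in reference order, optionally inverted.
    """
    rng = np.random.default_rng([config.seed, 1])
    lo_loss, hi_loss = config.break_loss
    cent = config.centromere

    contigs = SequenceSet()
    truth = SimTruth(
        true_blocks=[],
        true_order={},
        true_gaps={},
        true_inversions=[],
        true_dropped=[],
        true_losses=[],
        centromere_interval=None,
    )

    drops_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, length in config.dropped_intervals:
        if chrom not in reference:
            raise ValueError(f"dropped interval names unknown chromosome {chrom!r}")
        if length <= 0:
            raise ValueError("dropped interval lengths must be positive")
        drops_by_chrom.setdefault(chrom, []).append((start, start + length))
    for chrom, ivs in drops_by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"dropped intervals overlapping on {chrom}")

    for chrom in reference:
        length = reference.length(chrom)
        seq = reference.sequence(chrom)
        drops = drops_by_chrom.get(chrom, [])
        cent_iv = None
        if cent is not None and cent.chrom == chrom:
            cent_iv = (cent.position, cent.position + cent.array_length)
            truth.centromere_interval = GapInterval(chrom, *cent_iv)
        for s, e in drops:
            truth.true_dropped.append(GapInterval(chrom, s, e))

        segments = _kept_segments(length, drops, cent_iv)

        # rejection-sample cut positions until the requested count is reached:
        # each cut must sit in a normal segment, MIN_FRAGMENT from the segment
        # edges and from every other accepted cut
        n_cuts = config.n_fragments_per_chrom - 1
        accepted: list[int] = []
        attempts = 0
        while len(accepted) < n_cuts and attempts < 50 * max(n_cuts, 1):
            attempts += 1
            c = int(rng.integers(0, length))
            in_segment = any(
                kind == "normal" and s + MIN_FRAGMENT <= c <= e - MIN_FRAGMENT
                for s, e, kind in segments
            )
            if in_segment and all(abs(c - other) >= MIN_FRAGMENT for other in accepted):
                accepted.append(c)
        cuts_by_segment: dict[int, list[int]] = {}
        for c in sorted(accepted):
            for si, (s, e, kind) in enumerate(segments):
                if kind == "normal" and s <= c < e:
                    cuts_by_segment.setdefault(si, []).append(c)
                    break

        fragments: list[tuple[int, int]] = []  # reference intervals, in order
        for si, (s, e, kind) in enumerate(segments):
            if kind == "cent":
                edges = np.unique(np.linspace(s, e, cent.shatter_count + 1).astype(int))
                fragments.extend(
                    (int(a), int(b)) for a, b in zip(edges, edges[1:]) if b > a
                )
                continue
            pos = s
            for c in cuts_by_segment.get(si, []):
                fragments.append((pos, c))
                loss = int(rng.integers(lo_loss, hi_loss + 1)) if hi_loss > 0 else 0
                if loss > 0:
                    truth.true_losses.append(GapInterval(chrom, c, c + loss))
                pos = c + loss
            fragments.append((pos, e))

        order: list[tuple[str, str]] = []
        for k, (fs, fe) in enumerate(fragments):
            name = f"{chrom}_f{k:03d}"
            flen = fe - fs
            frag_seq = seq[fs:fe]
            invert = config.inversion_rate > 0 and rng.random() < config.inversion_rate

            if invert and config.inversion_mode == "contig":
                contigs.add(name, sequence=str(Seq(frag_seq).reverse_complement()))
                truth.true_blocks.append(
                    AlignmentBlock(chrom, fs, fe, name, 0, flen, REVERSE, 100.0,
                                   f"true:{name}:0")
                )
                truth.true_inversions.append(GapInterval(chrom, fs, fe))
                order.append((name, REVERSE))
            elif invert and config.inversion_mode == "internal" and flen >= 3000:
                margin = flen // 10
                inv_len = int(flen * (0.2 + 0.2 * rng.random()))
                inv_off = int(rng.integers(margin, flen - inv_len - margin + 1))
                a, b = fs + inv_off, fs + inv_off + inv_len
                contigs.add(
                    name,
                    sequence=seq[fs:a]
                    + str(Seq(seq[a:b]).reverse_complement())
                    + seq[b:fe],
                )
                truth.true_blocks.extend(
                    [
                        AlignmentBlock(chrom, fs, a, name, 0, a - fs, FORWARD, 100.0,
                                       f"true:{name}:0"),
                        AlignmentBlock(chrom, a, b, name, a - fs, b - fs, REVERSE, 100.0,
                                       f"true:{name}:1"),
                        AlignmentBlock(chrom, b, fe, name, b - fs, flen, FORWARD, 100.0,
                                       f"true:{name}:2"),
                    ]
                )
                truth.true_inversions.append(GapInterval(chrom, a, b))
                order.append((name, FORWARD))
            else:
                contigs.add(name, sequence=frag_seq)
                truth.true_blocks.append(
                    AlignmentBlock(chrom, fs, fe, name, 0, flen, FORWARD, 100.0,
                                   f"true:{name}:0")
                )
                order.append((name, FORWARD))

        truth.true_order[chrom] = order
        truth.true_gaps[chrom] = [
            nxt[0] - prv[1] for prv, nxt in zip(fragments, fragments[1:])
        ]

    if config.identity_noise > 0:
        truth = add_identity_noise(truth, config.identity_noise, config.seed)
    return contigs, truth


def add_identity_noise(truth: SimTruth, rate: float, seed: int) -> SimTruth:
    """Lower block identities as if bases were substituted binomially.

    Each block's identity becomes 100 * (1 - k / ref_len) with
    k ~ Binomial(ref_len, rate); the sequences themselves are untouched
    (the noise models the identity statistic, not the residues).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng([seed, 2])
    noisy = [
        dataclasses.replace(
            b, identity=100.0 * (1.0 - rng.binomial(b.ref_len, rate) / b.ref_len)
        )
        for b in truth.true_blocks
    ]
    return dataclasses.replace(truth, true_blocks=noisy)


def simulate(config: SimConfig) -> tuple[SequenceSet, SequenceSet, SimTruth]:
    """Reference + contigs + truth in one call."""
    reference = simulate_reference(config)
    contigs, truth = fragment_genome(reference, config)
    return reference, contigs, truth


def write_truth(reference: SequenceSet, contigs: SequenceSet, truth: SimTruth,
                outdir: str | Path) -> list[str]:
    """Write the fixture directory: FASTAs, truth block TSV, order TSV and
    BED truth tables.  Returns the written file names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(reference, outdir / "reference.fasta")
    write_fasta(contigs, outdir / "contigs.fasta")
    write_block_tsv(truth.true_blocks, outdir / "truth_blocks.tsv")
    with open(outdir / "truth_order.tsv", "w") as fh:
        fh.write("chrom\tposition\tcontig\torientation\n")
        for chrom in truth.true_order:
            for k, (name, orientation) in enumerate(truth.true_order[chrom]):
                fh.write(f"{chrom}\t{k}\t{name}\t{orientation}\n")
    write_bed(truth.true_dropped, outdir / "truth_dropped.bed")
    write_bed(truth.true_inversions, outdir / "truth_inversions.bed")
    with open(outdir / "reference_lengths.tsv", "w") as fh:
        for name, length, _ in reference.items():
            fh.write(f"{name}\t{length}\n")
    return [
        "reference.fasta",
        "contigs.fasta",
        "truth_blocks.tsv",
        "truth_order.tsv",
        "truth_dropped.bed",
        "truth_inversions.bed",
        "reference_lengths.tsv",
    ]
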
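"""Readers and writers for every on-disk format the toolkit touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open, which keeps interval
arithmetic (unions, complements, lengths) trivial.  On disk the tabular
formats follow the conventions of the tools they interoperate with:

* PAF is already 0-based half-open and is read as-is.
* The canonical block TSV and AGP use 1-based inclusive coordinates, the
  convention of printed per-chromosome report tables.
* BED is 0-based half-open, as the format requires.

The canonical block TSV dialect additionally accepts rows whose start is
larger than their end: such rows are interpreted as reverse-orientation
records and normalised to ascending coordinates, the way QUAST-style
alignment tables encode minus-strand blocks.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, TYPE_CHECKING

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .scaffolder import ScaffoldSet

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"

_STRAND = {FORWARD: "+", REVERSE: "-"}
_ORIENTATION = {"+": FORWARD, "-": REVERSE, FORWARD: FORWARD, REVERSE: REVERSE}

BLOCK_TSV_COLUMNS = (
    "ref_name",
    "ref_start",
    "ref_end",
    "query_name",
    "query_start",
    "query_end",
    "orientation",
    "identity",
)


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned segment between a contig and a reference chromosome.

    Coordinates are 0-based half-open and always ascending on both the
    reference and the query; ``orientation`` carries the strand.
    ``identity`` is a percentage in [0, 100].
    """

    ref_name: str
    ref_start: int
    ref_end: int
    query_name: str
    query_start: int
    query_end: int
    orientation: str
    identity: float
    block_id: str

    def __post_init__(self) -> None:
        if not self.ref_start < self.ref_end:
            raise ValueError(
                f"block {self.block_id}: ref interval not ascending "
                f"({self.ref_start}, {self.ref_end})"
            )
        if not self.query_start < self.query_end:
            raise ValueError(
                f"block {self.block_id}: query interval not ascending "
                f"({self.query_start}, {self.query_end})"
            )
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"block {self.block_id}: bad orientation {self.orientation!r}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"block {self.block_id}: identity {self.identity} outside [0, 100]")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_len(self) -> int:
        return self.query_end - self.query_start


class SequenceSet:
    """Ordered mapping name -> (length, optional sequence string).

    Carries contigs, reference chromosomes and scaffolds.  A record may be
    length-only (e.g. parsed from a name/length table); operations that need
    the residues raise if the string is absent.
    """

    def __init__(self) -> None:
        self._length: dict[str, int] = {}
        self._seq: dict[str, str | None] = {}

    @classmethod
    def from_sequences(cls, mapping: dict[str, str]) -> "SequenceSet":
        out = cls()
        for name, seq in mapping.items():
            out.add(name, sequence=seq)
        return out

    @classmethod
    def from_lengths(cls, mapping: dict[str, int]) -> "SequenceSet":
        out = cls()
        for name, length in mapping.items():
            out.add(name, length=length)
        return out

    def add(self, name: str, sequence: str | None = None, length: int | None = None) -> None:
        if name in self._length:
            raise ValueError(f"duplicate sequence name: {name!r}")
        if sequence is not None:
            if length is not None and length != len(sequence):
                raise ValueError(
                    f"{name!r}: stated length {length} != sequence length {len(sequence)}"
                )
            length = len(sequence)
        if length is None:
            raise ValueError(f"{name!r}: need a sequence or a length")
        if length <= 0:
            raise ValueError(f"{name!r}: non-positive length {length}")
        self._length[name] = int(length)
        self._seq[name] = sequence

    @property
    def names(self) -> list[str]:
        return list(self._length)

    def __len__(self) -> int:
        return len(self._length)

    def __contains__(self, name: str) -> bool:
        return name in self._length

    def __iter__(self) -> Iterator[str]:
        return iter(self._length)

    def length(self, name: str) -> int:
        if name not in self._length:
            raise KeyError(f"unknown sequence name: {name!r}")
        return self._length[name]

    def lengths(self) -> dict[str, int]:
        return dict(self._length)

    def has_sequence(self, name: str) -> bool:
        return self._seq.get(name) is not None

    def sequence(self, name: str) -> str:
        if name not in self._length:
            raise KeyError(f"unknown sequence name: {name!r}")
        seq = self._seq[name]
        if seq is None:
            raise ValueError(f"record {name!r} has no sequence string")
        return seq

    def items(self) -> Iterator[tuple[str, int, str | None]]:
        for name, length in self._length.items():
            yield name, length, self._seq[name]


@dataclass
class EvalConfig:
    """Thresholds shared across evaluation and scaffolding.

    min_contig          minimum contig length considered (bases)
    min_read_len        read-length floor for the read-filter utility (bases)
    min_uncovered_stretch
                        minimum length of an uncovered reference stretch worth
                        reporting (bases); also the gap size at which a block
                        end is annotated ``abuts_gap``
    colinear_gap_tolerance
                        maximum reference gap bridged when chaining colinear
                        blocks (bases)
    hotspot_window      window size for fragmentation-hotspot scanning (bases)
    hotspot_min_interruptions
                        block boundaries per window needed to call a hotspot
    min_gap_size        spacer inserted between abutting/overlapping contigs
                        during scaffolding (bases)
    min_assign_fraction minimum fraction of a contig's aligned length on its
                        best chromosome for a confident assignment
    """

    min_contig: int = 3000
    min_read_len: int = 500
    min_uncovered_stretch: int = 5000
    colinear_gap_tolerance: int = 100_000
    hotspot_window: int = 1_000_000
    hotspot_min_interruptions: int = 10
    min_gap_size: int = 100
    min_assign_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_contig",
            "min_read_len",
            "min_uncovered_stretch",
            "colinear_gap_tolerance",
            "hotspot_window",
            "hotspot_min_interruptions",
            "min_gap_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.min_assign_fraction <= 1.0:
            raise ValueError("min_assign_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvalConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _read_text(path: str | Path) -> str:
    """Read a text file, transparently decompressing plain gzip (.gz)."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a SequenceSet (sequences retained, case kept)."""
    out = SequenceSet()
    import io

    for record in SeqIO.parse(io.StringIO(_read_text(path)), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate header token {record.id!r} in {path}")
        out.add(record.id, sequence=str(record.seq))
    if len(out) == 0:
        raise ValueError(f"no records in {path}")
    return out


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seqs.sequence(name)), id=name, description="") for name in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_lengths_tsv(path: str | Path) -> SequenceSet:
    """Read a two-column name<TAB>length table into a length-only SequenceSet."""
    out = SequenceSet()
    for lineno, line in enumerate(_read_text(path).splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        out.add(parts[0], length=int(parts[1]))
    if len(out) == 0:
        raise ValueError(f"no records in {path}")
    return out


def filter_by_length(seqs: SequenceSet, min_len: int) -> SequenceSet:
    """Keep records with length >= min_len (inclusive floor), order preserved."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    out = SequenceSet()
    for name, length, seq in seqs.items():
        if length >= min_len:
            out.add(name, sequence=seq, length=length)
    return out


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Parse minimap2-style PAF into alignment blocks.

    Identity is computed as 100 * matches / alignment-length (columns 10/11);
    rows with zero alignment length are skipped with a warning.
    """
    blocks: list[AlignmentBlock] = []
    for lineno, line in enumerate(_read_text(path).splitlines(), 1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ValueError(f"{path}:{lineno}: expected >=12 tab-separated columns")
        try:
            qstart, qend = int(cols[2]), int(cols[3])
            tstart, tend = int(cols[7]), int(cols[8])
            nmatch, alnlen = int(cols[9]), int(cols[10])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate ({exc})") from None
        if alnlen == 0:
            logger.warning("%s:%d: zero alignment length, line skipped", path, lineno)
            continue
        blocks.append(
            AlignmentBlock(
                ref_name=cols[5],
                ref_start=tstart,
                ref_end=tend,
                query_name=cols[0],
                query_start=qstart,
                query_end=qend,
                orientation=FORWARD if cols[4] == "+" else REVERSE,
                identity=100.0 * nmatch / alnlen,
                block_id=f"paf:{lineno}",
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# Canonical block TSV
# ---------------------------------------------------------------------------

def read_block_tsv(path: str | Path) -> list[AlignmentBlock]:
    """Read the canonical block TSV dialect (1-based inclusive on disk).

    A row with descending reference or query coordinates is a minus-strand
    record: it is normalised to ascending coordinates with
    orientation=reverse.
    """
    lines = _read_text(path).splitlines()
    if not lines:
        raise ValueError(f"no header in {path}")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in BLOCK_TSV_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    idx = {c: header.index(c) for c in header}
    has_id = "block_id" in idx

    blocks: list[AlignmentBlock] = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        cols = line.split("\t")
        rs, re_ = int(cols[idx["ref_start"]]), int(cols[idx["ref_end"]])
        qs, qe = int(cols[idx["query_start"]]), int(cols[idx["query_end"]])
        orientation = _ORIENTATION[cols[idx["orientation"]]]
        if rs > re_ or qs > qe:
            orientation = REVERSE
            if rs > re_:
                rs, re_ = re_, rs
            if qs > qe:
                qs, qe = qe, qs
        blocks.append(
            AlignmentBlock(
                ref_name=cols[idx["ref_name"]],
                ref_start=rs - 1,
                ref_end=re_,
                query_name=cols[idx["query_name"]],
                query_start=qs - 1,
                query_end=qe,
                orientation=orientation,
                identity=float(cols[idx["identity"]]),
                block_id=cols[idx["block_id"]] if has_id else f"tsv:{lineno}",
            )
        )
    return blocks


def write_block_tsv(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    """Write blocks in the canonical dialect: 1-based inclusive, ascending."""
    with open(path, "w") as fh:
        fh.write("\t".join(BLOCK_TSV_COLUMNS + ("block_id",)) + "\n")
        for b in blocks:
            fh.write(
                "\t".join(
                    (
                        b.ref_name,
                        str(b.ref_start + 1),
                        str(b.ref_end),
                        b.query_name,
                        str(b.query_start + 1),
                        str(b.query_end),
                        _STRAND[b.orientation],
                        repr(b.identity),
                        b.block_id,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1
# ---------------------------------------------------------------------------

def write_agp(scaffolds: "ScaffoldSet", contig_lengths: SequenceSet, path: str | Path) -> None:
    """Write scaffolds as AGP v2.1 (W component lines, N scaffold-gap lines).

    Object coordinates are 1-based inclusive and contiguous from 1; every
    placed contig appears once, every inter-contig gap as an N line with
    gap_type "scaffold" and linkage "yes".
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for chrom in sorted(scaffolds.placements):
            obj = f"{chrom}_scaffold"
            pos = 1
            part = 1
            for pl in scaffolds.placements[chrom]:
                clen = contig_lengths.length(pl.query_name)
                if clen == 0:
                    raise ValueError(f"zero-length component {pl.query_name!r}")
                fh.write(
                    "\t".join(
                        (
                            obj,
                            str(pos),
                            str(pos + clen - 1),
                            str(part),
                            "W",
                            pl.query_name,
                            "1",
                            str(clen),
                            _STRAND[pl.orientation],
                        )
                    )
                    + "\n"
                )
                pos += clen
                part += 1
                if pl.gap_after is not None:
                    fh.write(
                        "\t".join(
                            (
                                obj,
                                str(pos),
                                str(pos + pl.gap_after - 1),
                                str(part),
                                "N",
                                str(pl.gap_after),
                                "scaffold",
                                "yes",
                                "align_genus",
                            )
                        )
                        + "\n"
                    )
                    pos += pl.gap_after
                    part += 1


def read_agp(path: str | Path) -> "ScaffoldSet":
    """Re-parse an AGP file into a ScaffoldSet (structure only).

    AGP does not record alignment anchors, so placements carry object
    coordinates as anchors and assign_fraction 1.0; order, orientation and
    gap sizes round-trip exactly.
    """
    from .scaffolder import Placement, ScaffoldSet

    per_obj: dict[str, list[Placement]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        obj, beg, end, _part, kind = cols[0], int(cols[1]), int(cols[2]), cols[3], cols[4]
        chrom = obj[: -len("_scaffold")] if obj.endswith("_scaffold") else obj
        if kind == "N":
            if not per_obj.get(chrom):
                raise ValueError(f"{path}: gap line before any component in {obj}")
            per_obj[chrom][-1].gap_after = int(cols[5])
            continue
        placements = per_obj.setdefault(chrom, [])
        placements.append(
            Placement(
                query_name=cols[5],
                chrom=chrom,
                order_index=len(placements),
                orientation=_ORIENTATION[cols[8]],
                anchor_start=beg - 1,
                anchor_end=end,
                assign_fraction=1.0,
                gap_after=None,
            )
        )
    return ScaffoldSet(placements=per_obj, unplaced=[], provenance={})


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable, path: str | Path) -> None:
    """Write intervals as BED3+ (0-based half-open).

    Accepts any objects with chrom/start/end attributes; an optional ``name``
    attribute becomes the fourth column.
    """
    with open(path, "w") as fh:
        for iv in intervals:
            row = [str(iv.chrom), str(iv.start), str(iv.end)]
            name = getattr(iv, "name", None)
            if name is not None:
                row.append(str(name))
            fh.write("\t".join(row) + "\n")
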
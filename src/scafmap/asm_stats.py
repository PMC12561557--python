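"""Whole-assembly contiguity statistics (Nx/Lx, totals, scaffold gap counts).

N_x is the length of the first contig, in descending length order, at which
the cumulative sum reaches at least x% of the total assembly length; L_x is
the 1-based rank of that contig.  The threshold is inclusive (>=), the
dominant convention, and is evaluated in exact integer arithmetic so ties
at exactly x% behave predictably.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SequenceSet

DEFAULT_X_VALUES = (50, 75, 90)

_N_RUN = re.compile(r"[Nn]+")


@dataclass
class AssemblyStats:
    total_length: int
    n_contigs: int
    longest: int
    nx: dict[int, int] = field(default_factory=dict)
    lx: dict[int, int] = field(default_factory=dict)
    n_gaps: int = 0

    def to_row(self) -> dict[str, int]:
        """Flatten into the column layout of the assembly report table."""
        row: dict[str, int] = {
            "assembly_length": self.total_length,
            "longest_contig": self.longest,
        }
        for x in sorted(self.nx):
            row[f"N{x}"] = self.nx[x]
        for x in sorted(self.lx):
            row[f"L{x}"] = self.lx[x]
        row["n_contigs"] = self.n_contigs
        row["n_gaps"] = self.n_gaps
        return row


def contiguity_stats(
    lengths: Sequence[int] | Iterable[int],
    x_values: Sequence[float] = DEFAULT_X_VALUES,
) -> AssemblyStats:
    """Compute total/longest and N_x/L_x for each requested x."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("no contigs")
    if np.any(arr < 1):
        raise ValueError("contig lengths must be >= 1")
    for x in x_values:
        if not 0 < x <= 100:
            raise ValueError(f"x value {x} outside (0, 100]")

    desc = np.sort(arr)[::-1]
    csum = np.cumsum(desc)
    total = int(csum[-1])

    nx: dict[int, int] = {}
    lx: dict[int, int] = {}
    for x in x_values:
        # first index where 100 * cumulative >= x * total, all in int64
        idx = int(np.searchsorted(csum * 100, x * total, side="left"))
        nx[int(x)] = int(desc[idx])
        lx[int(x)] = idx + 1
    return AssemblyStats(
        total_length=total,
        n_contigs=int(arr.size),
        longest=int(desc[0]),
        nx=nx,
        lx=lx,
        n_gaps=0,
    )


def count_scaffold_gaps(seqs: SequenceSet) -> int:
    """Total number of maximal N-runs across all sequences (case-insensitive)."""
    total = 0
    for name, _length, seq in seqs.items():
        if seq is None:
            raise ValueError(f"record {name!r} has no sequence string")
        total += len(_N_RUN.findall(seq))
    return total
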
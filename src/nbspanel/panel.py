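"""Target-panel construction and interval arithmetic.

A panel is the set of genomic intervals over which calling and QC are
restricted: each exon padded by a few bases on either side (5 bp by default)
plus any 3'UTR intervals, merged into a sorted non-overlapping list. BED
coordinates are 0-based half-open; VCF positions are 1-based. Conversions
happen only at the I/O boundary and in the variant-footprint overlap logic.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import MalformedInputError
from .variants import VariantRecord


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise MalformedInputError(
                f"invalid interval {self.contig}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Sort and merge overlapping or abutting intervals."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].contig == iv.contig and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.contig, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return tuple(merged)


@dataclass(frozen=True)
class PanelDefinition:
    """A named target panel: sorted, merged intervals plus the padding used."""

    name: str
    intervals: tuple[GenomicInterval, ...]
    padding_bp: int = 5

    def __post_init__(self) -> None:
        if self.padding_bp < 0:
            raise MalformedInputError("padding must be non-negative")
        if tuple(merge_intervals(self.intervals)) != self.intervals:
            raise MalformedInputError("panel intervals must be sorted and merged")

    @property
    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @cached_property
    def _contig_index(self) -> dict[str, tuple[list[int], list[int]]]:
        idx: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            starts, ends = idx.setdefault(iv.contig, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)
        return idx

    def contains(self, contig: str, pos0: int) -> bool:
        """Membership of a 0-based position, by binary search."""
        idx = self._contig_index.get(contig)
        if idx is None:
            return False
        starts, ends = idx
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]

    def overlaps(self, contig: str, start0: int, end0: int) -> bool:
        """True when the half-open interval [start0, end0) touches any panel base."""
        idx = self._contig_index.get(contig)
        if idx is None:
            return False
        starts, ends = idx
        i = bisect.bisect_right(starts, end0 - 1) - 1
        return i >= 0 and ends[i] > start0

    def positions(self) -> Iterator[tuple[str, int]]:
        """Iterate (contig, 0-based position) over every panel base."""
        for iv in self.intervals:
            for p in range(iv.start, iv.end):
                yield (iv.contig, p)


def build_panel(
    exons: Sequence[GenomicInterval], padding_bp: int = 5, name: str = "panel"
) -> PanelDefinition:
    """Pad each exon by ``padding_bp`` on both sides (clamped at 0) and merge."""
    if padding_bp < 0:
        raise MalformedInputError("padding must be non-negative")
    padded = [
        GenomicInterval(iv.contig, max(0, iv.start - padding_bp), iv.end + padding_bp)
        for iv in exons
    ]
    return PanelDefinition(name=name, intervals=merge_intervals(padded), padding_bp=padding_bp)


def restrict_calls(
    calls: Sequence[VariantRecord], panel: PanelDefinition
) -> list[VariantRecord]:
    """Keep calls whose reference footprint overlaps at least one panel base.

    The footprint of a call is pos .. pos+len(ref)-1 (1-based), so a deletion
    is retained when any deleted base lies inside the panel, mirroring the
    default behaviour of interval-intersection tools. Input order is kept.
    """
    out = []
    for v in calls:
        s0, e0 = v.footprint0()
        if panel.overlaps(v.contig, s0, e0):
            out.append(v)
    return out


def read_bed(path: str | Path, name: str | None = None, padding_bp: int = 0) -> PanelDefinition:
    """Read a >=3-column BED file into a panel (track/browser lines ignored).

    The intervals are merged as read; ``padding_bp`` is recorded as metadata
    only (BED files are assumed to already contain the padded coordinates).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedInputError(f"BED line has fewer than 3 columns: {line!r}")
            rows.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return PanelDefinition(
        name=name or Path(path).stem, intervals=merge_intervals(rows), padding_bp=padding_bp
    )


def write_bed(panel: PanelDefinition, path: str | Path) -> None:
    """Write panel intervals as 3-column BED."""
    df = pd.DataFrame(
        [(iv.contig, iv.start, iv.end) for iv in panel.intervals],
        columns=["chrom", "start", "end"],
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def intervals_to_exon_list(
    raw: Sequence[tuple[str, int, int]]
) -> list[GenomicInterval]:
    """Convenience constructor from (contig, start, end) tuples."""
    return [GenomicInterval(c, s, e) for c, s, e in raw]
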
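"""Reference sequences and local sequence-context queries.

Contigs are plain uppercase nucleotide strings addressed 1-based inclusive,
the convention used for anchoring VCF-style variant records. Homopolymer
context matters because semiconductor sequencing chemistries mis-call
insertions/deletions inside long single-nucleotide runs, and the variant
filter carries a cap on the permitted run length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import BoundsError

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceSequence:
    """A single reference contig.

    Parameters
    ----------
    name
        Contig name as it appears in FASTA/VCF/BED files.
    sequence
        Uppercase nucleotide string over the alphabet ``{A, C, G, T, N}``.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"invalid characters in reference sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Return the base at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise BoundsError(f"position {pos} outside contig {self.name!r} (length {len(self.sequence)})")
        return self.sequence[pos - 1]

    def slice1(self, start: int, end: int) -> str:
        """Return bases for the 1-based inclusive range ``[start, end]``."""
        if start > end:
            raise BoundsError(f"empty 1-based range [{start}, {end}]")
        if start < 1 or end > len(self.sequence):
            raise BoundsError(
                f"range [{start}, {end}] outside contig {self.name!r} (length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]


def homopolymer_length(ref: ReferenceSequence, pos: int) -> int:
    """Length of the maximal single-nucleotide run containing 1-based ``pos``.

    Example: on ``GTTTTTTC`` position 4 lies in the six-base poly-T run, so the
    result is 6; on ``ACGT`` every position returns 1.
    """
    seq = ref.sequence
    if not 1 <= pos <= len(seq):
        raise BoundsError(f"position {pos} outside contig {ref.name!r} (length {len(seq)})")
    i = pos - 1
    base = seq[i]
    lo = i
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = i
    while hi + 1 < len(seq) and seq[hi + 1] == base:
        hi += 1
    return hi - lo + 1
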
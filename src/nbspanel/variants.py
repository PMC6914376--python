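"""Variant records, multi-allelic decomposition, and left-align/trim normalization.

Two call sets can only be compared allele-by-allele once every record is in a
canonical form. The canonical form used throughout this package is the
standard one for small variants: biallelic, parsimonious (no shared leading or
trailing bases beyond the required anchor) and left-aligned (shifted as far
left along the reference as an equivalent representation exists). The
normalization algorithm is the classic left-align-and-trim loop:

1. while REF and ALT end in the same base, drop that base; if either allele
   becomes empty, prepend the reference base to the left of the current
   position to both alleles and move the position one base left;
2. while REF and ALT both have length >= 2 and start with the same base, drop
   that base and move the position one base right.

The result is the unique leftmost parsimonious representation of the edit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import LeftExtensionError, MalformedInputError, ReferenceMismatchError
from .reference import ReferenceSequence

HET = "het"
HOM = "hom"
UNKNOWN = "unknown"

SNV = "SNV"
INDEL = "indel"

_ALLELE_ALPHABET = frozenset("ACGTN")


def _check_allele(allele: str, label: str) -> None:
    if not allele:
        raise MalformedInputError(f"{label} allele must be non-empty")
    bad = set(allele) - _ALLELE_ALPHABET
    if bad:
        raise MalformedInputError(f"invalid characters in {label} allele: {sorted(bad)}")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic small-variant call.

    ``pos`` is 1-based and points at the first reference base of ``ref``.
    ``depth_per_strand`` holds (forward, reverse) read counts at the site and
    ``strand_bias`` is the caller's bias statistic in [0, 1].
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str = UNKNOWN
    qual: float = 100.0
    allele_fraction: float = 0.5
    depth: int = 100
    depth_per_strand: tuple[int, int] = (50, 50)
    strand_bias: float = 0.0

    def __post_init__(self) -> None:
        _check_allele(self.ref, "ref")
        _check_allele(self.alt, "alt")
        if self.ref == self.alt:
            raise MalformedInputError(f"ref and alt identical at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise MalformedInputError(f"position must be >= 1, got {self.pos}")
        if self.genotype not in (HET, HOM, UNKNOWN):
            raise MalformedInputError(f"invalid genotype {self.genotype!r}")
        if self.qual < 0:
            raise MalformedInputError("qual must be non-negative")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise MalformedInputError("allele_fraction must lie in [0, 1]")
        if self.depth < 0 or min(self.depth_per_strand) < 0:
            raise MalformedInputError("depths must be non-negative")
        if not 0.0 <= self.strand_bias <= 1.0:
            raise MalformedInputError("strand_bias must lie in [0, 1]")

    @property
    def variant_class(self) -> str:
        """``SNV`` for 1 bp substitutions, ``indel`` otherwise."""
        return SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele-level match key (contig, pos, ref, alt)."""
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference footprint."""
        return self.pos + len(self.ref) - 1

    def footprint0(self) -> tuple[int, int]:
        """Reference footprint as a 0-based half-open interval."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def is_parsimonious(self) -> bool:
        """True when no shared trailing base, and no shared leading base while
        both alleles have length >= 2 (the reference-free part of normality)."""
        if self.ref[-1] == self.alt[-1]:
            return False
        if len(self.ref) >= 2 and len(self.alt) >= 2 and self.ref[0] == self.alt[0]:
            return False
        return True


@dataclass(frozen=True)
class RawVariantCall:
    """A possibly multi-allelic call as read from a VCF row.

    ``genotype_indices`` follows VCF GT semantics: 0 is the reference allele,
    i >= 1 the i-th alternate; ``None`` entries are no-calls.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotype_indices: tuple[int | None, ...] = (None, None)
    qual: float = 100.0
    allele_fractions: tuple[float, ...] | None = None
    depth: int = 100
    depth_per_strand: tuple[int, int] = (50, 50)
    strand_bias: float = 0.0

    def __post_init__(self) -> None:
        if not self.alts:
            raise MalformedInputError(f"no alternate alleles at {self.contig}:{self.pos}")
        _check_allele(self.ref, "ref")
        for a in self.alts:
            _check_allele(a, "alt")


def decompose(raw: RawVariantCall) -> list[VariantRecord]:
    """Split a multi-allelic call into one biallelic record per alternate.

    The genotype of each output reflects only its own allele: present on both
    haplotypes -> hom, on one -> het, absent or no-call -> unknown. Output
    order follows the input ALT order. Genotype indices beyond the listed
    alleles raise :class:`MalformedInputError`.
    """
    n_alt = len(raw.alts)
    indices = [i for i in raw.genotype_indices if i is not None]
    for i in indices:
        if i < 0 or i > n_alt:
            raise MalformedInputError(
                f"genotype index {i} out of range for {n_alt} alt allele(s) at {raw.contig}:{raw.pos}"
            )
    has_call = len(indices) == len(raw.genotype_indices) and len(indices) > 0
    afs = raw.allele_fractions
    if afs is not None and len(afs) != n_alt:
        raise MalformedInputError("allele_fractions length must match number of alt alleles")
    out: list[VariantRecord] = []
    for i, alt in enumerate(raw.alts, start=1):
        if has_call:
            count = indices.count(i)
            genotype = HOM if count == 2 else HET if count == 1 else UNKNOWN
        else:
            genotype = UNKNOWN
        out.append(
            VariantRecord(
                contig=raw.contig,
                pos=raw.pos,
                ref=raw.ref,
                alt=alt,
                genotype=genotype,
                qual=raw.qual,
                allele_fraction=afs[i - 1] if afs is not None else 0.5,
                depth=raw.depth,
                depth_per_strand=raw.depth_per_strand,
                strand_bias=raw.strand_bias,
            )
        )
    return out


def _check_ref_match(v: VariantRecord, ref: ReferenceSequence) -> None:
    expected = ref.slice1(v.pos, v.end)
    if expected != v.ref:
        raise ReferenceMismatchError(
            f"REF {v.ref!r} at {v.contig}:{v.pos} does not match reference {expected!r}"
        )


def normalize(v: VariantRecord, ref: ReferenceSequence) -> VariantRecord:
    """Return the leftmost parsimonious representation of ``v``.

    Idempotent; SNVs are fixed points. Raises
    :class:`~nbspanel.errors.ReferenceMismatchError` when ``v.ref`` disagrees
    with the reference and :class:`~nbspanel.errors.LeftExtensionError` when
    left alignment would walk past position 1 of the contig.
    """
    _check_ref_match(v, ref)
    pos, r, a = v.pos, v.ref, v.alt
    # right-trim shared suffix, extending left from the reference on emptiness
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
        if not r or not a:
            if pos == 1:
                raise LeftExtensionError(
                    f"cannot left-align past start of contig {v.contig!r} (variant at pos {v.pos})"
                )
            pos -= 1
            base = ref.base(pos)
            r, a = base + r, base + a
    # left-trim shared prefix while both alleles keep an anchor base
    while len(r) >= 2 and len(a) >= 2 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    if (pos, r, a) == (v.pos, v.ref, v.alt):
        return v
    return replace(v, pos=pos, ref=r, alt=a)


def split_mnp(v: VariantRecord) -> list[VariantRecord]:
    """Decompose an equal-length multi-base substitution into per-base SNVs.

    Positions where REF and ALT agree are dropped. Non-MNP records are
    returned unchanged as a single-element list. Per-base decomposition makes
    truth-set matching independent of whether a caller reports adjacent
    substitutions as one block or several.
    """
    if len(v.ref) != len(v.alt) or len(v.ref) == 1:
        return [v]
    out = []
    for i, (rb, ab) in enumerate(zip(v.ref, v.alt)):
        if rb != ab:
            out.append(replace(v, pos=v.pos + i, ref=rb, alt=ab))
    return out


def apply_variant(sequence: str, pos: int, ref: str, alt: str) -> str:
    """Apply an edit to a contig string; the equivalence oracle's primitive."""
    i = pos - 1
    if sequence[i : i + len(ref)] != ref:
        raise ReferenceMismatchError(f"REF {ref!r} does not match sequence at pos {pos}")
    return sequence[:i] + alt + sequence[i + len(ref) :]


def normalize_records(
    records: Iterable[VariantRecord], ref: ReferenceSequence
) -> list[VariantRecord]:
    """Pipeline normalization: left-align/trim every record, then split MNPs.

    The SNVs produced by MNP splitting are already normalized (SNVs are fixed
    points), so a single pass suffices.
    """
    out: list[VariantRecord] = []
    for v in records:
        out.extend(split_mnp(normalize(v, ref)))
    return out


def decompose_and_normalize(
    raw_calls: Sequence[RawVariantCall], ref: ReferenceSequence
) -> list[VariantRecord]:
    """Full canonicalization of raw VCF rows: decompose then normalize."""
    flat: list[VariantRecord] = []
    for raw in raw_calls:
        flat.extend(decompose(raw))
    return normalize_records(flat, ref)
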
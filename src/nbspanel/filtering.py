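"""Post-hoc threshold filter replicating a variant caller's acceptance rules.

The thresholds mirror a sensitivity-tuned caller configuration for an
amplicon assay: a low quality floor (10), allele fraction >= 0.1, total depth
>= 10, no per-strand depth requirement, strand-bias checks disabled (max bias
1 with p-value 0), and rejection of calls sitting in homopolymer runs longer
than 9 bp — the characteristic error mode of semiconductor sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError
from .reference import ReferenceSequence, homopolymer_length
from .variants import VariantRecord

#: rejection reason codes, in evaluation order
REASON_QUAL = "qual"
REASON_AF = "allele_fraction"
REASON_DEPTH = "depth"
REASON_STRAND_DEPTH = "strand_depth"
REASON_STRAND_BIAS = "strand_bias"
REASON_HOMOPOLYMER = "homopolymer"


@dataclass(frozen=True)
class FilterThresholds:
    """Caller acceptance thresholds.

    ``strand_bias_pvalue`` is carried for configuration fidelity; at its
    default 0 together with ``max_strand_bias`` = 1 the strand-bias test never
    rejects. ``homopolymer_applies_to`` selects which variant classes the
    homopolymer cap is applied to ("snv", "indel" or "both").
    """

    min_qual: float = 10.0
    min_allele_fraction: float = 0.1
    min_depth: int = 10
    min_depth_each_strand: int = 0
    max_strand_bias: float = 1.0
    strand_bias_pvalue: float = 0.0
    max_homopolymer_len: int = 9
    homopolymer_applies_to: str = "both"

    def __post_init__(self) -> None:
        if min(self.min_qual, self.min_allele_fraction, self.min_depth,
               self.min_depth_each_strand, self.max_strand_bias,
               self.strand_bias_pvalue, self.max_homopolymer_len) < 0:
            raise ConfigError("thresholds must be non-negative")
        if self.min_allele_fraction > 1 or self.max_strand_bias > 1:
            raise ConfigError("fractional thresholds must be <= 1")
        if self.homopolymer_applies_to not in ("snv", "indel", "both"):
            raise ConfigError("homopolymer_applies_to must be 'snv', 'indel' or 'both'")


def _homopolymer_site(v: VariantRecord, ref: ReferenceSequence) -> int:
    # first base of the alt-affected reference footprint: the variant position
    # for substitutions, the base after the anchor for indels
    if len(v.ref) == len(v.alt):
        return v.pos
    return min(v.pos + 1, len(ref))


def _failure_reason(
    v: VariantRecord, t: FilterThresholds, ref: ReferenceSequence | None
) -> str | None:
    if v.qual < t.min_qual:
        return REASON_QUAL
    if v.allele_fraction < t.min_allele_fraction:
        return REASON_AF
    if v.depth < t.min_depth:
        return REASON_DEPTH
    if min(v.depth_per_strand) < t.min_depth_each_strand:
        return REASON_STRAND_DEPTH
    if v.strand_bias > t.max_strand_bias:
        return REASON_STRAND_BIAS
    if ref is not None:
        applies = t.homopolymer_applies_to == "both" or (
            t.homopolymer_applies_to == "snv") == (v.variant_class == "SNV")
        if applies and homopolymer_length(ref, _homopolymer_site(v, ref)) > t.max_homopolymer_len:
            return REASON_HOMOPOLYMER
    return None


def filter_calls(
    candidates: list[VariantRecord],
    thresholds: FilterThresholds | None = None,
    ref: ReferenceSequence | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Partition candidate calls into (passed, rejected-with-reason).

    Criteria are evaluated in a fixed order (qual, allele fraction, depth,
    per-strand depth, strand bias, homopolymer context); a rejected call
    carries the first criterion it failed. Order is preserved within both
    lists, and passed + rejected is a partition of the input. The homopolymer
    criterion is skipped when no reference is supplied.
    """
    t = thresholds or FilterThresholds()
    passed: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, str]] = []
    for v in candidates:
        reason = _failure_reason(v, t, ref)
        if reason is None:
            passed.append(v)
        else:
            rejected.append((v, reason))
    return passed, rejected
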
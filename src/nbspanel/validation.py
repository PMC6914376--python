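"""Truth-set benchmarking: confusion matrix and summary statistics.

Calls are matched to a truth catalogue on the allele-level key
(contig, pos, ref, alt) after normalization, so equivalent representations
compare equal. True negatives are counted at base resolution: every panel
position not touched by the footprint of any TP/FP/FN event counts once as a
correctly-reported reference base. On a panel of N bases with all events at
distinct single positions this gives the conservation identity
tp + fp + fn + tn = N.

Derived statistics use the standard definitions

    sensitivity = 100 * TP / (TP + FN)
    specificity = 100 * TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any factor of the denominator vanishes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import PreconditionError
from .panel import GenomicInterval, PanelDefinition
from .reference import ReferenceSequence, homopolymer_length
from .variants import VariantRecord


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts from comparing a call set to a truth set over a panel."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def sensitivity(cm: ConfusionMatrix) -> float:
    """Percent of truth variants recovered; undefined with an empty truth set."""
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no truth variants (tp + fn = 0)")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """Percent of negative panel positions correctly reported reference."""
    if cm.tn + cm.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative positions (tn + fp = 0)")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 by convention when degenerate."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def _require_parsimonious(records: Sequence[VariantRecord], label: str) -> None:
    for v in records:
        if not v.is_parsimonious():
            raise PreconditionError(
                f"{label} call {v.contig}:{v.pos} {v.ref}>{v.alt} is not normalized"
            )


def _footprint_positions(v: VariantRecord, panel: PanelDefinition) -> set[tuple[str, int]]:
    s0, e0 = v.footprint0()
    return {(v.contig, p) for p in range(s0, e0) if panel.contains(v.contig, p)}


def compare_to_truth(
    query: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    panel: PanelDefinition,
) -> ConfusionMatrix:
    """Confusion matrix of a query call set against a truth set over a panel.

    Both inputs must be normalized and panel-restricted. Matching is on
    (contig, pos, ref, alt); genotype is deliberately not part of the key.
    TN = panel bases minus the distinct panel positions consumed by any
    TP/FP/FN footprint.
    """
    _require_parsimonious(query, "query")
    _require_parsimonious(truth, "truth")
    qkeys = {v.key for v in query}
    tkeys = {v.key for v in truth}
    tp = len(qkeys & tkeys)
    fp = len(qkeys - tkeys)
    fn = len(tkeys - qkeys)
    consumed: set[tuple[str, int]] = set()
    for v in list(query) + list(truth):
        consumed |= _footprint_positions(v, panel)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=panel.total_bases - len(consumed))


def zygosity_mismatches(
    query: Sequence[VariantRecord], truth: Sequence[VariantRecord]
) -> list[tuple[VariantRecord, VariantRecord]]:
    """Allele-matched pairs whose genotypes disagree (reported separately,
    never as fp + fn)."""
    truth_by_key = {v.key: v for v in truth}
    out = []
    for q in query:
        t = truth_by_key.get(q.key)
        if t is not None and q.genotype != t.genotype and "unknown" not in (q.genotype, t.genotype):
            out.append((q, t))
    return out


def flag_context(
    fp_calls: Sequence[VariantRecord],
    ref: ReferenceSequence | dict[str, ReferenceSequence],
    str_regions: Sequence[GenomicInterval] = (),
    min_homopolymer: int = 5,
) -> list[tuple[VariantRecord, dict[str, bool]]]:
    """Annotate false positives with repeat-context flags.

    ``in_str`` marks calls whose footprint overlaps a declared short-tandem-
    repeat interval; ``in_homopolymer`` marks calls sitting in a
    single-nucleotide run of at least ``min_homopolymer`` bases. Artifact
    calls in such tracts are candidates for exclusion in a targeted analysis.
    """
    refs = ref if isinstance(ref, dict) else {ref.name: ref}
    out = []
    for v in fp_calls:
        s0, e0 = v.footprint0()
        in_str = any(
            iv.contig == v.contig and iv.start < e0 and iv.end > s0 for iv in str_regions
        )
        contig_ref = refs.get(v.contig)
        in_homopolymer = False
        if contig_ref is not None:
            for pos in range(v.pos, min(v.end, len(contig_ref)) + 1):
                if homopolymer_length(contig_ref, pos) >= min_homopolymer:
                    in_homopolymer = True
                    break
        out.append((v, {"in_str": in_str, "in_homopolymer": in_homopolymer}))
    return out


@dataclass
class ValidationReport:
    """Full benchmarking result for one query/truth comparison."""

    confusion: ConfusionMatrix
    sensitivity_pct: float
    specificity_pct: float
    mcc: float
    unique_matching_variants: int
    fp_breakdown: list[tuple[VariantRecord, dict[str, bool]]] = field(default_factory=list)
    zygosity_mismatch_count: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            },
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "mcc": self.mcc,
            "unique_matching_variants": self.unique_matching_variants,
            "zygosity_mismatch_count": self.zygosity_mismatch_count,
            "fp_breakdown": [
                {
                    "contig": v.contig,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    **flags,
                }
                for v, flags in self.fp_breakdown
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        c = self.confusion
        lines = [
            "metric\tvalue",
            f"tp\t{c.tp}",
            f"fp\t{c.fp}",
            f"fn\t{c.fn}",
            f"tn\t{c.tn}",
            f"sensitivity_pct\t{self.sensitivity_pct:.4f}",
            f"specificity_pct\t{self.specificity_pct:.4f}",
            f"mcc\t{self.mcc:.4f}",
            f"unique_matching_variants\t{self.unique_matching_variants}",
        ]
        return "\n".join(lines) + "\n"


def validate(
    query: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    panel: PanelDefinition,
    ref: ReferenceSequence | dict[str, ReferenceSequence] | None = None,
    str_regions: Sequence[GenomicInterval] = (),
) -> ValidationReport:
    """Compare, derive statistics, and annotate false-positive context."""
    cm = compare_to_truth(query, truth, panel)
    tkeys = {v.key for v in truth}
    fp_calls = [v for v in query if v.key not in tkeys]
    breakdown = (
        flag_context(fp_calls, ref, str_regions) if ref is not None
        else [(v, {"in_str": False, "in_homopolymer": False}) for v in fp_calls]
    )
    unique_matching = len({v.key for v in query} & tkeys)
    return ValidationReport(
        confusion=cm,
        sensitivity_pct=sensitivity(cm) if cm.tp + cm.fn else 0.0,
        specificity_pct=specificity(cm) if cm.tn + cm.fp else 0.0,
        mcc=mcc(cm),
        unique_matching_variants=unique_matching,
        fp_breakdown=breakdown,
        zygosity_mismatch_count=len(zygosity_mismatches(query, truth)),
    )
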
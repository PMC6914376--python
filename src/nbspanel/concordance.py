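"""Coverage-stratified concordance between paired call sets.

The motivating design compares, for each individual, calls made from a dried
blood spot (sample A) against calls from venous blood (sample B). Concordance
for a pair is the percentage of variants matching, formalised over the union:
100 * |A intersect B| / |A union B|. Each variant present in only one member
becomes a discordance event classified by direction, variant class, and a
coverage stratum derived from the *minimum* of the two samples' depths at the
site — a variant is only reliably assessable when both members clear the
depth floor (30x by default). High-coverage concordance is computed over the
union variants in the high stratum only; most discordance in practice sits in
the low stratum, so the stratified figure exceeds the all-regions one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .coverage import CoverageTrack
from .errors import ConfigError
from .variants import VariantRecord

ONLY_IN_A = "only_in_A"
ONLY_IN_B = "only_in_B"
STRATUM_LOW = "low"
STRATUM_HIGH = "high"


@dataclass(frozen=True)
class ConcordancePolicy:
    """Depth thresholds for stratification.

    ``coverage_threshold`` splits the low stratum (min depth <= threshold)
    from the high stratum; ``high_coverage_threshold`` defines an additional
    stricter "high coverage only" summary. ``denominator`` selects the
    concordance denominator: "union" (default) or "mean" for
    2|A&B| / (|A|+|B|).
    """

    coverage_threshold: int = 30
    high_coverage_threshold: int = 50
    denominator: str = "union"

    def __post_init__(self) -> None:
        if self.coverage_threshold <= 0 or self.high_coverage_threshold <= 0:
            raise ConfigError("coverage thresholds must be positive")
        if self.denominator not in ("union", "mean"):
            raise ConfigError("denominator must be 'union' or 'mean'")


@dataclass(frozen=True)
class DiscordanceEvent:
    variant: VariantRecord
    direction: str  # only_in_A | only_in_B
    variant_class: str  # SNV | indel
    stratum: str  # low | high
    coverage_a: int
    coverage_b: int


@dataclass
class PairedComparison:
    """Concordance result for one sample pair."""

    pair_id: str
    n_calls_total: int  # |A| + |B|
    n_union: int
    n_concordant_unique: int  # |A & B|
    concordance_all_pct: float
    concordance_high_cov_pct: float
    concordance_over_high_threshold_pct: float
    events: list[DiscordanceEvent] = field(default_factory=list)
    per_category_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "pair_id": self.pair_id,
            "n_calls_total": self.n_calls_total,
            "n_union": self.n_union,
            "n_concordant_unique": self.n_concordant_unique,
            "concordance_all_pct": self.concordance_all_pct,
            "concordance_high_cov_pct": self.concordance_high_cov_pct,
            "concordance_over_high_threshold_pct": self.concordance_over_high_threshold_pct,
            "events": [
                {
                    "contig": e.variant.contig,
                    "pos": e.variant.pos,
                    "ref": e.variant.ref,
                    "alt": e.variant.alt,
                    "direction": e.direction,
                    "variant_class": e.variant_class,
                    "stratum": e.stratum,
                    "coverage_a": e.coverage_a,
                    "coverage_b": e.coverage_b,
                }
                for e in self.events
            ],
            "per_category_counts": {
                "|".join(k): v for k, v in sorted(self.per_category_counts.items())
            },
        }


def _pct(num: int, den: int) -> float:
    # empty denominator: nothing assessable, no observable discordance
    return 100.0 if den == 0 else 100.0 * num / den


def compare_pair(
    calls_a: Sequence[VariantRecord],
    calls_b: Sequence[VariantRecord],
    depth_a: CoverageTrack,
    depth_b: CoverageTrack,
    policy: ConcordancePolicy | None = None,
    pair_id: str = "pair",
) -> PairedComparison:
    """Concordance between two normalized, panel-restricted call sets.

    Matching is allele-level on (contig, pos, ref, alt). Every union-minus-
    intersection variant yields one :class:`DiscordanceEvent`. Depth lookups
    are strict: a call position with no depth data raises a data-integrity
    error.
    """
    policy = policy or ConcordancePolicy()
    a_by_key = {v.key: v for v in calls_a}
    b_by_key = {v.key: v for v in calls_b}
    union_keys = set(a_by_key) | set(b_by_key)
    inter_keys = set(a_by_key) & set(b_by_key)

    def site_info(key: tuple[str, int, str, str]) -> tuple[int, int, str]:
        contig, pos, _, _ = key
        ca = depth_a.depth(contig, pos - 1, strict=True)
        cb = depth_b.depth(contig, pos - 1, strict=True)
        stratum = STRATUM_LOW if min(ca, cb) <= policy.coverage_threshold else STRATUM_HIGH
        return ca, cb, stratum

    events: list[DiscordanceEvent] = []
    n_high = n_high_concordant = 0
    n_vhigh = n_vhigh_concordant = 0
    for key in sorted(union_keys):
        ca, cb, stratum = site_info(key)
        concordant = key in inter_keys
        if stratum == STRATUM_HIGH:
            n_high += 1
            n_high_concordant += concordant
        if min(ca, cb) > policy.high_coverage_threshold:
            n_vhigh += 1
            n_vhigh_concordant += concordant
        if not concordant:
            v = a_by_key.get(key) or b_by_key[key]
            events.append(
                DiscordanceEvent(
                    variant=v,
                    direction=ONLY_IN_A if key in a_by_key else ONLY_IN_B,
                    variant_class=v.variant_class,
                    stratum=stratum,
                    coverage_a=ca,
                    coverage_b=cb,
                )
            )

    if policy.denominator == "union":
        all_pct = _pct(len(inter_keys), len(union_keys))
    else:
        all_pct = _pct(2 * len(inter_keys), len(a_by_key) + len(b_by_key))
    counts = Counter((e.direction, e.variant_class, e.stratum) for e in events)
    return PairedComparison(
        pair_id=pair_id,
        n_calls_total=len(calls_a) + len(calls_b),
        n_union=len(union_keys),
        n_concordant_unique=len(inter_keys),
        concordance_all_pct=all_pct,
        concordance_high_cov_pct=_pct(n_high_concordant, n_high),
        concordance_over_high_threshold_pct=_pct(n_vhigh_concordant, n_vhigh),
        events=events,
        per_category_counts=dict(counts),
    )


def cohort_concordance(pairs: Sequence[PairedComparison]) -> dict:
    """Cohort summary: mean per-pair concordances, pooled event-category
    counts, and total call numbers (total, union, concordant-only)."""
    if not pairs:
        raise ConfigError("cohort_concordance needs at least one pair")
    pooled: Counter = Counter()
    for p in pairs:
        pooled.update(p.per_category_counts)
    return {
        "n_pairs": len(pairs),
        "mean_concordance_all_pct": sum(p.concordance_all_pct for p in pairs) / len(pairs),
        "mean_concordance_high_cov_pct": sum(p.concordance_high_cov_pct for p in pairs) / len(pairs),
        "n_calls_total": sum(p.n_calls_total for p in pairs),
        "n_union_total": sum(p.n_union for p in pairs),
        "n_concordant_total": sum(p.n_concordant_unique for p in pairs),
        "n_discordant_total": sum(len(p.events) for p in pairs),
        "per_category_counts": dict(pooled),
    }
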
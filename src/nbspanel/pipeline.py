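"""End-to-end analyses wiring the stages together.

Stage order for every call set is fixed: read -> decompose -> normalize ->
filter -> restrict to panel -> compare -> report. Filtering precedes panel
restriction (caller-then-intersect); ``restrict_first`` swaps the two for
sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

from .concordance import ConcordancePolicy, PairedComparison, cohort_concordance, compare_pair
from .coverage import CoverageTrack, QCPolicy, run_summary, sample_qc
from .errors import ConfigError
from .filtering import FilterThresholds, filter_calls
from .panel import PanelDefinition, restrict_calls
from .reference import ReferenceSequence
from .validation import ValidationReport, validate
from .variants import RawVariantCall, VariantRecord, decompose_and_normalize
from . import vcfio

logger = logging.getLogger("nbspanel")


def prepare_calls(
    raw_calls: Sequence[RawVariantCall],
    refs: Mapping[str, ReferenceSequence],
    panel: PanelDefinition,
    thresholds: FilterThresholds | None = None,
    restrict_first: bool = False,
    label: str = "calls",
) -> list[VariantRecord]:
    """Canonicalize raw calls and apply filter + panel restriction."""
    by_contig: dict[str, list[RawVariantCall]] = {}
    for raw in raw_calls:
        by_contig.setdefault(raw.contig, []).append(raw)
    normalized: list[VariantRecord] = []
    for contig, group in by_contig.items():
        if contig not in refs:
            raise ConfigError(f"no reference contig {contig!r} for {label}")
        normalized.extend(decompose_and_normalize(group, refs[contig]))
    logger.info("%s: %d raw -> %d normalized", label, len(raw_calls), len(normalized))

    def _filter(records: list[VariantRecord]) -> list[VariantRecord]:
        passed_all: list[VariantRecord] = []
        n_rej = 0
        for contig, grp in _group(records).items():
            passed, rejected = filter_calls(grp, thresholds, refs.get(contig))
            passed_all.extend(passed)
            n_rej += len(rejected)
        logger.info("%s: filter passed %d, rejected %d", label, len(passed_all), n_rej)
        return passed_all

    if restrict_first:
        records = _filter(restrict_calls(normalized, panel))
    else:
        records = restrict_calls(_filter(normalized), panel)
    logger.info("%s: %d calls in panel", label, len(records))
    return sorted(records, key=lambda v: v.key)


def _group(records: Sequence[VariantRecord]) -> dict[str, list[VariantRecord]]:
    out: dict[str, list[VariantRecord]] = {}
    for v in records:
        out.setdefault(v.contig, []).append(v)
    return out


def run_validate(
    reference_fasta: str | Path,
    panel_bed: str | Path,
    query_vcf: str | Path,
    truth_vcf: str | Path,
    out_dir: str | Path | None = None,
    thresholds: FilterThresholds | None = None,
) -> ValidationReport:
    """Truth-set benchmarking of one query call set."""
    for p in (reference_fasta, panel_bed, query_vcf, truth_vcf):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    refs = vcfio.read_fasta(reference_fasta)
    from .panel import read_bed

    panel = read_bed(panel_bed)
    query = prepare_calls(vcfio.read_vcf(query_vcf), refs, panel, thresholds, label="query")
    # the truth catalogue is canonicalized and restricted but never filtered
    truth = prepare_calls(
        vcfio.read_vcf(truth_vcf), refs, panel,
        thresholds=FilterThresholds(0, 0, 0, 0, 1.0, 0, 10**9), label="truth",
    )
    report = validate(query, truth, panel, ref=refs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "validation.json").write_text(report.to_json())
        (out_dir / "validation.tsv").write_text(report.to_tsv())
    return report


def run_concord(
    reference_fasta: str | Path,
    panel_bed: str | Path,
    pairs: Sequence[tuple[str, str | Path, str | Path, str | Path, str | Path]],
    out_dir: str | Path | None = None,
    thresholds: FilterThresholds | None = None,
    policy: ConcordancePolicy | None = None,
) -> tuple[list[PairedComparison], dict]:
    """Cohort concordance analysis.

    ``pairs`` rows are (pair_id, vcf_a, vcf_b, depth_tsv_a, depth_tsv_b).
    """
    if not pairs:
        raise ConfigError("no sample pairs supplied")
    refs = vcfio.read_fasta(reference_fasta)
    from .panel import read_bed

    panel = read_bed(panel_bed)
    results = []
    for pair_id, vcf_a, vcf_b, dep_a, dep_b in pairs:
        calls_a = prepare_calls(vcfio.read_vcf(vcf_a), refs, panel, thresholds, label=f"{pair_id}/A")
        calls_b = prepare_calls(vcfio.read_vcf(vcf_b), refs, panel, thresholds, label=f"{pair_id}/B")
        track_a = CoverageTrack.from_tsv(dep_a)
        track_b = CoverageTrack.from_tsv(dep_b)
        results.append(compare_pair(calls_a, calls_b, track_a, track_b, policy, pair_id=pair_id))
    summary = cohort_concordance(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for r in results:
            (out_dir / f"{r.pair_id}.json").write_text(json.dumps(r.to_dict(), indent=2))
        (out_dir / "cohort.json").write_text(json.dumps(_jsonable(summary), indent=2))
        (out_dir / "cohort.tsv").write_text(_cohort_tsv(results))
    return results, summary


def _jsonable(summary: dict) -> dict:
    out = dict(summary)
    out["per_category_counts"] = {
        "|".join(k): v for k, v in sorted(summary["per_category_counts"].items())
    }
    return out


def _cohort_tsv(results: Sequence[PairedComparison]) -> str:
    lines = ["pair_id\tn_calls_total\tn_union\tn_concordant\tconcordance_all_pct\tconcordance_high_cov_pct"]
    for r in results:
        lines.append(
            f"{r.pair_id}\t{r.n_calls_total}\t{r.n_union}\t{r.n_concordant_unique}"
            f"\t{r.concordance_all_pct:.4f}\t{r.concordance_high_cov_pct:.4f}"
        )
    return "\n".join(lines) + "\n"


def run_coverage_qc(
    panel_bed: str | Path,
    depth_tsvs: Sequence[str | Path],
    policy: QCPolicy | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Per-sample coverage QC plus run-level tier summary."""
    from .panel import read_bed

    panel = read_bed(panel_bed)
    policy = policy or QCPolicy()
    samples = [sample_qc(CoverageTrack.from_tsv(p), panel, policy) for p in depth_tsvs]
    summary = run_summary(samples, policy)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lines = ["sample_id\tpct_bases_at_depth\ttier"]
        lines += [f"{s.sample_id}\t{s.pct_bases_at_depth:.4f}\t{s.tier}" for s in samples]
        (out_dir / "coverage_qc.tsv").write_text("\n".join(lines) + "\n")
        (out_dir / "coverage_qc.json").write_text(json.dumps(summary, indent=2))
    return summary
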
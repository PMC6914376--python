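# Methods

This note documents the models, conventions and numerical choices behind
`nbspanel`, and what the synthetic data do and do not establish.

## Variant canonicalization

Call sets from different callers, or from re-processing the same sample, can
write one edit many ways. Records are reduced to a canonical form in two
steps. Multi-allelic rows are first decomposed into one biallelic record per
alternate allele; the genotype of each output reflects only its own allele
(on both haplotypes → hom, one → het, absent or no-call → unknown — the
convention is ours, documented because callers differ). Each biallelic record
is then left-aligned and trimmed: shared trailing bases are removed,
extending one reference base leftward whenever an allele would empty, then
shared leading bases are removed while both alleles retain an anchor. The
result is the unique leftmost parsimonious representation; the operation is
idempotent and SNVs are fixed points. Equal-length multi-base substitutions
are subsequently split into per-base SNVs (`split_mnp`), making truth
matching independent of whether adjacent substitutions are reported as a
block. An edit that cannot be left-aligned without walking past position 1
of the contig raises an error rather than emitting a partial representation:
explicit failure beats silently wrong coordinates.

The test suite checks this against an independent oracle: all equivalent
representations of an edit are enumerated by applying them to the contig
string and comparing edited sequences, and the normalizer's output must
equal the minimal-length, leftmost representation, on more than a thousand
random contigs including repeat-rich ones.

## Panel model and coordinates

VCF positions are 1-based inclusive; BED intervals are 0-based half-open.
Conversions happen only at the I/O boundary. A panel is built by padding
each exon by `padding_bp` (default 5) on both sides, clamping at zero, and
merging overlapping or abutting intervals; `total_bases` is the merged
length and is the denominator for all per-base statistics. A call is "in
panel" when any reference base of its footprint (pos … pos+len(ref)−1) lies
in a panel interval, mirroring the default behaviour of interval
intersection tools; 3′UTR targets are ordinary intervals with no special
treatment.

## Threshold filter

The filter reproduces a sensitivity-tuned caller configuration as a
deterministic post-hoc stage: quality ≥ 10, allele fraction ≥ 0.1, depth
≥ 10, per-strand depth ≥ 0, strand bias ≤ 1 with p-value 0 (the last two are
carried for configuration fidelity but are no-ops at these most-permissive
values), and homopolymer run length ≤ 9 at the variant site. Criteria are
evaluated in a fixed order and a rejected call carries the first criterion
it failed. Homopolymer context is taken at the first base of the
alt-affected reference footprint (the variant position for substitutions,
the base after the anchor for indels); whether the cap applies to SNVs,
indels or both is configurable and defaults to both.

## Truth-set benchmarking

Matching is allele-level on `(contig, pos, ref, alt)` after normalization;
genotype is deliberately not part of the key (zygosity mismatches are
reported separately, never as FP+FN), and a configuration switch can tighten
this. True negatives are counted at base resolution: every panel position
not consumed by the footprint of a TP/FP/FN event counts once as a correctly
reported reference base, and an indel footprint consumes all its spanned
positions. With all events at distinct single positions this yields the
conservation identity tp+fp+fn+tn = panel bases, which the tests assert.
MCC returns 0 when any denominator factor vanishes. Sensitivity and
specificity raise on empty denominators rather than guessing. False
positives are annotated with `in_str` (footprint overlaps a declared
short-tandem-repeat interval) and `in_homopolymer` (run ≥ 5 bp) flags so
reports can show exclusion-eligible artifacts.

## Paired concordance

Per-pair concordance is 100·|A∩B|/|A∪B| — the union denominator is
symmetric and reads directly as "percentage of variants matching"; a
`denominator="mean"` option (2|A∩B|/(|A|+|B|)) is available for sensitivity
analysis. Each union-minus-intersection variant becomes one discordance
event classified by direction, variant class and stratum. The stratum uses
the **minimum** of the two samples' depths at the site against the 30×
floor: a variant is only reliably assessable when both members clear it. An
additional ">50× only" percentage is reported for high-coverage summaries.
An empty denominator (no assessable variants) reports 100%: no observable
discordance. Cohort summaries are unweighted means of per-pair percentages
plus pooled event-category counts; total calls are reported as |A|+|B|,
union, and concordant-only counts since all three conventions exist in
practice.

## Coverage QC

A sample's statistic is the percent of panel bases with depth ≥ 50 (depth
comparisons are inclusive). Tiers: below 90% fail; 90–97% may have gaps;
97–99.5% minor gaps; at or above 99.5% clean. A sample exactly at a cutoff
belongs to the better tier, consistent with "below the cutoff fails".
Run-level summaries report, for each cutoff, the cumulative proportion of
samples at or above it (these are nested, hence monotone non-increasing as
the cutoff tightens) plus exclusive tier counts. Depth input is a long
per-base table (chrom, pos 0-based, depth, sample_id); positions absent from
the table are depth 0.

## Operations model

Turnaround is the inclusive day span of the stage schedule (default:
booking/punching/extraction/library start on day 1, digestion/barcoding/
QC/pooling/chip loading on day 2, sequencing and data processing on day 3,
analysis and reporting on day 4 → 4 days); a repeat is two full sequential
cycles (8 days). Weekly throughput is samples/run × runs/day × days/week ×
sequencers (defaults 96 × 2 × 7 × 1 = 1344 gross), deflated by the repeat
rate for unique samples (⌊1344·(1−3/96)⌋ = 1302). Cost aggregation sums the
included items, inflating repeat-sensitive ones by 1/(1−r); the itemization
itself is user-supplied and the example values in `examples/05_ops_model.py`
are placeholders — only the aggregation arithmetic is guaranteed.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure of a small-gene screening panel study:
five genes (3–27 exons each, 65 exons total) on separate contigs, exon
lengths drawn log-normally and scaled so the padded panel hits exactly
50,054 bases (introns always exceed twice the padding, so padded exons never
merge); an exonic poly-T tract of 8 bp (long enough to be artifact-prone,
short enough to pass the 9 bp homopolymer cap, so the planted false-positive
indels survive filtering); an intronic 10 bp poly-T and an intronic (CA)₁₂
STR to exercise the cap and the STR flagging; a truth catalogue of 130 SNVs
and 2 small indels at well-separated panel positions; and 33 sample pairs of
two specimen types. Random contigs are post-processed so no accidental
homopolymer exceeds 6 bp — the only long runs are the declared ones, which
keeps filter behaviour fully under the generator's control.

Depth is modelled per 200 bp window (an amplicon surrogate): window means
are gamma-distributed around 300× (shape 8, an overdispersed but unimodal
choice; no specific depth distribution is claimed, only threshold
behaviour), with per-base Poisson noise. A fixed set of windows (2% of panel
windows, at least one containing a truth SNV) is systematically
low-coverage: mean 15×, capped at the 30× stratification floor so
"low-coverage region" and "low stratum" coincide by construction. False
negatives are injected with probability 0.25 in low-coverage windows and
0.005 elsewhere; false-positive SNVs arrive at ~0.1 per sample at random
panel positions with low allele fractions; false-positive indels arrive at
~0.05 per sample, always at the same position in the exonic poly-T tract.
Reported call depths are floored at the caller minimum of 10, since a real
caller would not emit a call below its own depth threshold. Injected false
positives are written to the VCFs in randomized equivalent (denormalized)
representations so the in-pipeline normalizer does real work.

The ledger records every injected error, and stratum labels are computed
from the *emitted* depth tracks exactly as the concordance analysis computes
them, so recovery tests can demand exact equality, not approximation.

What passing these tests shows: the pipeline's accounting is exact under a
known error process, its stratification is consistent, and its statistics
follow from the counts. What it does not show: performance on real
sequencing data — the generator has no read-level error model, no alignment
artifacts, no amplicon dropout correlated with GC or SNPs under primers, and
specimen-type differences are injected, not mechanistic. Real-data
concordance and specificity therefore cannot be inferred from synthetic
results.

## Numerical and interface conventions

- VCF FORMAT fields carry allele fraction and strand bias quantized to four
  decimals and quality to three, so write→read round-trips are exact despite
  float32 VCF storage.
- Problem sizes used by the test suite and the acceptance script: the full
  study scale (50 kb panel, 33 pairs, 288-sample QC run) — generation and
  analysis complete in seconds — with a 6 kb, 4-pair configuration for unit
  tests.
- The worked-example MCC on counts (tp=130, fp=10, fn=0, tn=49905) is
  0.96353; summaries that quote three decimals may show 0.963 (truncation)
  or 0.964 (rounding). Tests assert agreement within 0.001.
- Degenerate inputs fail loudly: empty panels, empty schedules, empty
  cohorts and missing depth at a call site raise typed errors with distinct
  CLI exit codes (2 config, 3 data integrity, 4 precondition).

## Known limitations

No haplotype-aware matching of complex regions; no symbolic alleles,
breakends or phasing; no BAM-level processing (depth tables are the input
boundary); concordance and validation treat samples independently (no joint
genotyping); the operations model is deterministic arithmetic, not a
queueing simulation.
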
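"""Synthetic data generation for end-to-end pipeline exercise.

Real newborn-screening panel data (dried-blood-spot and venous-blood call
sets over a multi-gene exonic panel) are not publicly distributable, so every
input the pipeline consumes is generated here: reference contigs with
engineered repeat tracts, an exon panel of ~50 kb with 5 bp padding, a truth
variant catalogue dominated by SNVs, paired per-sample call sets with
coverage-dependent false negatives and rare false positives, and per-base
depth tracks with a small number of systematically low-coverage regions.

Everything is driven by one integer seed, and a :class:`GroundTruthLedger`
records exactly which errors were injected where, so downstream statistics
can be checked for exact recovery rather than merely plausible values.

Design of the error model: false negatives occur with a high probability in
designated low-coverage windows and a small probability elsewhere; false
positive SNVs appear at random panel positions at a low per-sample rate; and
false-positive indels appear only at a designated exonic poly-T tract,
mimicking the characteristic homopolymer artifact of semiconductor
sequencing. Injected false positives are written to the VCFs in randomized
equivalent (denormalized) representations so the normalizer is exercised
in-pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .coverage import CoverageTrack
from .errors import ConfigError, DataIntegrityError
from .panel import GenomicInterval, PanelDefinition, build_panel
from .reference import ReferenceSequence
from .variants import HET, HOM, VariantRecord, normalize
from . import vcfio

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults model a five-gene exonic screening panel of 50,054 target bases
    (exons padded by 5 bp), a truth catalogue of 130 SNVs and 2 indels, 33
    paired samples of two specimen types, a mean read depth of 300x with a
    2% fraction of systematically low-coverage windows (mean 15x, capped at
    the 30x stratification floor), and error probabilities concentrating
    false negatives in the low-coverage stratum.
    """

    seed: int = 0
    n_genes: int = 5
    exons_per_gene: tuple[int, ...] = (27, 13, 12, 10, 3)
    panel_padding: int = 5
    target_panel_bases: int = 50054
    n_truth_snvs: int = 130
    n_truth_indels: int = 2
    hom_fraction: float = 0.3
    n_pairs: int = 33
    # depth model
    depth_window: int = 200
    mean_depth: float = 300.0
    depth_dispersion: float = 8.0
    fraction_low_coverage_windows: float = 0.02
    low_mean_depth: float = 15.0
    low_depth_cap: int = 30
    # error model
    p_fn_low: float = 0.25
    p_fn_high: float = 0.005
    p_fp_snv: float = 0.1
    p_fp_indel_polyt: float = 0.05
    # engineered repeat tracts
    polyt_exonic_len: int = 8
    polyt_intronic_len: int = 10
    str_unit: str = "CA"
    str_repeats: int = 12
    min_intron: int = 200
    max_intron: int = 800

    def __post_init__(self) -> None:
        for p in (self.hom_fraction, self.fraction_low_coverage_windows,
                  self.p_fn_low, self.p_fn_high, self.p_fp_snv, self.p_fp_indel_polyt):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if len(self.exons_per_gene) != self.n_genes:
            raise ConfigError("exons_per_gene must have n_genes entries")
        # introns must host the engineered tracts with margins, and must be
        # wide enough that padded exons never merge
        if self.min_intron < self.str_repeats * len(self.str_unit) + 2 * self.panel_padding + 60:
            raise ConfigError("min_intron too small to host engineered tracts")


@dataclass
class SyntheticReference:
    """Generated contigs plus declared annotation intervals (0-based)."""

    references: dict[str, ReferenceSequence]
    exons: list[GenomicInterval]
    str_regions: list[GenomicInterval]
    homopolymer_regions: list[GenomicInterval]
    #: (contig, 1-based position of first T, length) of the exonic poly-T tract
    polyt_site: tuple[str, int, int]


def _cap_runs(bases: np.ndarray, max_run: int = 6) -> np.ndarray:
    """Break any single-nucleotide run longer than ``max_run`` so the only
    long homopolymers in a contig are the engineered ones."""
    out = bases.copy()
    run = 1
    for i in range(1, out.size):
        if out[i] == out[i - 1]:
            run += 1
            if run > max_run:
                out[i] = (out[i] + 1) % 4
                run = 1
        else:
            run = 1
    return out


def _exon_lengths(rng: np.random.Generator, cfg: SimulationConfig) -> list[int]:
    n_exons = sum(cfg.exons_per_gene)
    total = cfg.target_panel_bases - 2 * cfg.panel_padding * n_exons
    if total < 40 * n_exons:
        raise ConfigError("target_panel_bases too small for the requested exon count")
    weights = rng.lognormal(mean=0.0, sigma=0.6, size=n_exons)
    raw = weights / weights.sum() * total
    lengths = np.maximum(np.floor(raw).astype(int), 40)
    # fix the sum exactly by adjusting the largest exon
    lengths[int(np.argmax(lengths))] += total - int(lengths.sum())
    if lengths.min() < 40:
        raise ConfigError("exon length allocation failed; increase target_panel_bases")
    return [int(x) for x in lengths]


def make_reference(cfg: SimulationConfig) -> SyntheticReference:
    """Generate contigs (one per gene) with exons separated by introns large
    enough that padded exons never merge, plus engineered STR and poly-T
    tracts. Deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    lengths = _exon_lengths(rng, cfg)
    exons: list[GenomicInterval] = []
    references: dict[str, ReferenceSequence] = {}
    exon_bounds_per_gene: list[list[tuple[int, int]]] = []
    li = 0
    for g in range(cfg.n_genes):
        contig = f"gene{g + 1}"
        cursor = 0
        bounds: list[tuple[int, int]] = []
        for _ in range(cfg.exons_per_gene[g]):
            cursor += int(rng.integers(cfg.min_intron, cfg.max_intron + 1))
            bounds.append((cursor, cursor + lengths[li]))
            cursor += lengths[li]
            li += 1
        cursor += int(rng.integers(cfg.min_intron, cfg.max_intron + 1))
        seq = _cap_runs(rng.integers(0, 4, size=cursor))
        references[contig] = seq  # placeholder; finalized below
        exon_bounds_per_gene.append(bounds)
        exons.extend(GenomicInterval(contig, s, e) for s, e in bounds)

    str_regions: list[GenomicInterval] = []
    homopolymer_regions: list[GenomicInterval] = []

    def _write_tract(seq: np.ndarray, start: int, tract: str, flank: str) -> None:
        codes = {b: i for i, b in enumerate("ACGT")}
        for j, b in enumerate(tract):
            seq[start + j] = codes[b]
        seq[start - 1] = codes[flank]
        seq[start + len(tract)] = codes[flank]

    # exonic poly-T tract in the longest exon (in panel; hosts FP indels)
    all_exons = sorted(exons, key=lambda iv: iv.length, reverse=True)
    host = all_exons[0]
    pt_start = host.start + host.length // 2
    _write_tract(references[host.contig], pt_start, "T" * cfg.polyt_exonic_len, "C")
    polyt_site = (host.contig, pt_start + 1, cfg.polyt_exonic_len)
    homopolymer_regions.append(
        GenomicInterval(host.contig, pt_start, pt_start + cfg.polyt_exonic_len)
    )

    # intronic long poly-T (outside panel; exercises the homopolymer cap)
    g0_bounds = exon_bounds_per_gene[0]
    hp_contig = "gene1"
    hp_start = g0_bounds[0][1] + cfg.panel_padding + 30
    _write_tract(references[hp_contig], hp_start, "T" * cfg.polyt_intronic_len, "G")
    homopolymer_regions.append(
        GenomicInterval(hp_contig, hp_start, hp_start + cfg.polyt_intronic_len)
    )

    # intronic STR upstream of a mid-gene exon (outside panel)
    sg = min(3, cfg.n_genes - 1)
    sg_bounds = exon_bounds_per_gene[sg]
    anchor_exon = sg_bounds[min(7, len(sg_bounds) - 1)]
    tract = cfg.str_unit * cfg.str_repeats
    str_start = anchor_exon[0] - cfg.panel_padding - 20 - len(tract)
    _write_tract(references[f"gene{sg + 1}"], str_start, tract, "G")
    str_regions.append(GenomicInterval(f"gene{sg + 1}", str_start, str_start + len(tract)))

    final = {
        name: ReferenceSequence(name, "".join(_BASES[arr]))
        for name, arr in references.items()
    }
    return SyntheticReference(
        references=final,
        exons=exons,
        str_regions=str_regions,
        homopolymer_regions=homopolymer_regions,
        polyt_site=polyt_site,
    )


@dataclass
class GroundTruthLedger:
    """Exact record of the injected ground truth.

    ``samples`` maps sample id to its injected false negatives/positives;
    ``pairs`` lists, for each pair, every discordant variant with direction,
    variant class and its depth stratum computed exactly as the concordance
    analysis does (minimum of the two members' depths vs. the threshold).
    """

    truth_keys: list[list]
    samples: dict[str, dict]
    pairs: list[dict]
    low_coverage_windows: list[list]
    stratum_threshold: int = 30

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": 1,
                "truth_keys": self.truth_keys,
                "samples": self.samples,
                "pairs": self.pairs,
                "low_coverage_windows": self.low_coverage_windows,
                "stratum_threshold": self.stratum_threshold,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLedger":
        d = json.loads(text)
        return cls(
            truth_keys=d["truth_keys"],
            samples=d["samples"],
            pairs=d["pairs"],
            low_coverage_windows=d["low_coverage_windows"],
            stratum_threshold=d["stratum_threshold"],
        )


@dataclass
class SyntheticCohort:
    """Everything the pipeline needs, in memory."""

    config: SimulationConfig
    reference: SyntheticReference
    panel: PanelDefinition
    truth: list[VariantRecord]
    calls: dict[str, list[VariantRecord]]  # normalized call sets per sample
    emitted_calls: dict[str, list[VariantRecord]]  # as written to VCF (FPs denormalized)
    depths: dict[str, CoverageTrack]
    ledger: GroundTruthLedger
    pair_ids: list[tuple[str, str, str]]  # (pair_id, sample_a, sample_b)


def _pick_spaced_positions(
    rng: np.random.Generator,
    candidates: list[tuple[str, int]],
    n: int,
    taken: dict[str, set[int]],
    spacing: int = 12,
) -> list[tuple[str, int]]:
    order = rng.permutation(len(candidates))
    picked: list[tuple[str, int]] = []
    for idx in order:
        contig, pos0 = candidates[int(idx)]
        occupied = taken.setdefault(contig, set())
        if any((pos0 + d) in occupied for d in range(-spacing, spacing + 1)):
            continue
        occupied.add(pos0)
        picked.append((contig, pos0))
        if len(picked) == n:
            return picked
    raise ConfigError(
        f"could not place {n} variants with spacing {spacing}; panel too small for config"
    )


def make_truth(
    cfg: SimulationConfig, synref: SyntheticReference, panel: PanelDefinition,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Plant a truth catalogue of SNVs and a few small indels at well-spaced
    panel positions, avoiding the engineered poly-T tract. All records are
    normalized."""
    pt_contig, pt_pos1, pt_len = synref.polyt_site
    excluded = {(pt_contig, p) for p in range(pt_pos1 - 4, pt_pos1 + pt_len + 3)}
    candidates = [
        (c, p) for c, p in panel.positions()
        if (c, p) not in excluded and p >= 2
    ]
    n_total = cfg.n_truth_snvs + cfg.n_truth_indels
    taken: dict[str, set[int]] = {}
    spots = _pick_spaced_positions(rng, candidates, n_total, taken)
    truth: list[VariantRecord] = []
    for i, (contig, pos0) in enumerate(spots):
        ref_seq = synref.references[contig]
        genotype = HOM if rng.random() < cfg.hom_fraction else HET
        af = 1.0 if genotype == HOM else 0.5
        pos1 = pos0 + 1
        if i < cfg.n_truth_snvs:
            rb = ref_seq.base(pos1)
            alt = str(rng.choice([b for b in "ACGT" if b != rb]))
            v = VariantRecord(contig, pos1, rb, alt, genotype=genotype,
                              qual=100.0, allele_fraction=af, depth=100)
        else:
            if rng.random() < 0.5:  # 1 bp insertion
                rb = ref_seq.base(pos1)
                alt = rb + str(rng.choice(list("ACGT")))
                v = VariantRecord(contig, pos1, rb, alt, genotype=genotype,
                                  qual=100.0, allele_fraction=af, depth=100)
            else:  # 1 bp deletion
                rb = ref_seq.slice1(pos1, pos1 + 1)
                v = VariantRecord(contig, pos1, rb, rb[0], genotype=genotype,
                                  qual=100.0, allele_fraction=af, depth=100)
        truth.append(normalize(v, ref_seq))
    truth.sort(key=lambda v: v.key)
    if len({v.key for v in truth}) != len(truth):
        raise DataIntegrityError("truth placement produced duplicate keys")
    return truth


def _panel_windows(
    cfg: SimulationConfig, synref: SyntheticReference, panel: PanelDefinition
) -> list[tuple[str, int]]:
    """(contig, window index) for every depth window touching the panel."""
    out = []
    for contig, ref in synref.references.items():
        n_win = math.ceil(len(ref) / cfg.depth_window)
        for w in range(n_win):
            if panel.overlaps(contig, w * cfg.depth_window, (w + 1) * cfg.depth_window):
                out.append((contig, w))
    return out


def _choose_low_windows(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    windows: list[tuple[str, int]],
    truth: Sequence[VariantRecord],
) -> set[tuple[str, int]]:
    k = max(1, round(cfg.fraction_low_coverage_windows * len(windows)))
    snv_windows = sorted(
        {(v.contig, (v.pos - 1) // cfg.depth_window)
         for v in truth if v.variant_class == "SNV"}
    )
    low: set[tuple[str, int]] = set()
    # guarantee at least one low-coverage window hosts a truth SNV so the
    # low stratum is never empty of assessable variants
    low.add(snv_windows[int(rng.integers(len(snv_windows)))])
    rest = [w for w in windows if w not in low]
    order = rng.permutation(len(rest))
    for idx in order[: max(0, k - 1)]:
        low.add(rest[int(idx)])
    return low


def _make_depth_track(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    synref: SyntheticReference,
    low_windows: set[tuple[str, int]],
    sample_id: str,
) -> CoverageTrack:
    depths: dict[str, np.ndarray] = {}
    shape = cfg.depth_dispersion
    for contig, ref in synref.references.items():
        size = len(ref)
        n_win = math.ceil(size / cfg.depth_window)
        means = rng.gamma(shape, cfg.mean_depth / shape, size=n_win)
        arr = np.empty(size, dtype=np.int64)
        for w in range(n_win):
            lo, hi = w * cfg.depth_window, min((w + 1) * cfg.depth_window, size)
            if (contig, w) in low_windows:
                d = rng.poisson(cfg.low_mean_depth, size=hi - lo)
                arr[lo:hi] = np.minimum(d, cfg.low_depth_cap)
            else:
                arr[lo:hi] = rng.poisson(means[w], size=hi - lo)
        depths[contig] = arr
    return CoverageTrack(sample_id, depths)


def _call_metadata(
    rng: np.random.Generator, v: VariantRecord, track: CoverageTrack, min_depth: int = 10
) -> VariantRecord:
    # reported DP is floored at the caller's minimum: a call below it would
    # never have been emitted
    dp = max(track.depth(v.contig, v.pos - 1), min_depth)
    fwd = int(rng.binomial(dp, 0.5))
    if v.genotype == HOM:
        af = round(float(rng.uniform(0.92, 1.0)), 4)
    else:
        af = round(float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7)), 4)
    return replace(
        v,
        qual=round(float(rng.uniform(30, 100)), 1),
        allele_fraction=af,
        depth=dp,
        depth_per_strand=(fwd, dp - fwd),
        strand_bias=round(float(rng.uniform(0.0, 0.05)), 4),
    )


def denormalize(
    v: VariantRecord, ref: ReferenceSequence, rng: np.random.Generator
) -> VariantRecord:
    """An equivalent but non-canonical representation of ``v``: identity,
    shared trailing base, shared leading base, or (for indels in repeat
    tracts) a right-shifted form. normalize() inverts it."""
    choice = int(rng.integers(0, 3))
    if choice == 1 and v.end < len(ref):  # shared trailing base
        nxt = ref.base(v.end + 1)
        return replace(v, ref=v.ref + nxt, alt=v.alt + nxt)
    if choice == 2 and v.pos > 1:  # shared leading base
        prev = ref.base(v.pos - 1)
        return replace(v, pos=v.pos - 1, ref=prev + v.ref, alt=prev + v.alt)
    return v


def _fp_snv(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    synref: SyntheticReference,
    panel_positions: list[tuple[str, int]],
    taken: dict[str, set[int]],
) -> VariantRecord | None:
    for _ in range(200):
        contig, pos0 = panel_positions[int(rng.integers(len(panel_positions)))]
        occupied = taken.setdefault(contig, set())
        if any((pos0 + d) in occupied for d in range(-12, 13)):
            continue
        occupied.add(pos0)
        ref_seq = synref.references[contig]
        rb = ref_seq.base(pos0 + 1)
        alt = str(rng.choice([b for b in "ACGT" if b != rb]))
        return VariantRecord(
            contig, pos0 + 1, rb, alt, genotype=HET,
            qual=round(float(rng.uniform(12, 60)), 1),
            allele_fraction=round(float(rng.uniform(0.1, 0.35)), 4),
        )
    return None


def _fp_polyt_indel(cfg: SimulationConfig, synref: SyntheticReference) -> VariantRecord:
    # normalized single-T insertion anchored just left of the poly-T tract;
    # every affected sample gets the identical call (same position)
    contig, pos1, _ = synref.polyt_site
    ref_seq = synref.references[contig]
    anchor = pos1 - 1
    base = ref_seq.base(anchor)
    return VariantRecord(
        contig, anchor, base, base + "T", genotype=HET,
        qual=35.0, allele_fraction=0.15,
    )


def make_truth_and_calls(
    cfg: SimulationConfig,
    synref: SyntheticReference,
    panel: PanelDefinition,
) -> SyntheticCohort:
    """Generate the full paired cohort: truth set, two call sets and two depth
    tracks per pair, and the ground-truth ledger describing every injected
    error."""
    rng = np.random.default_rng(cfg.seed + 1)
    truth = make_truth(cfg, synref, panel, rng)
    truth_taken: dict[str, set[int]] = {}
    for v in truth:
        truth_taken.setdefault(v.contig, set()).add(v.pos - 1)

    windows = _panel_windows(cfg, synref, panel)
    low_windows = _choose_low_windows(cfg, rng, windows, truth)
    regimes = {
        v.key: ("low" if (v.contig, (v.pos - 1) // cfg.depth_window) in low_windows else "high")
        for v in truth
    }
    panel_positions = list(panel.positions())

    calls: dict[str, list[VariantRecord]] = {}
    emitted: dict[str, list[VariantRecord]] = {}
    depths: dict[str, CoverageTrack] = {}
    sample_ledgers: dict[str, dict] = {}
    pair_ids: list[tuple[str, str, str]] = []

    for i in range(cfg.n_pairs):
        pair_ids.append((f"pair{i + 1:02d}", f"DBS{i + 1:02d}", f"VB{i + 1:02d}"))

    for pair_id, sid_a, sid_b in pair_ids:
        for sid in (sid_a, sid_b):
            track = _make_depth_track(cfg, rng, synref, low_windows, sid)
            depths[sid] = track
            taken = {c: set(s) for c, s in truth_taken.items()}
            sample_calls: list[VariantRecord] = []
            fn_ledger: list[dict] = []
            fp_ledger: list[dict] = []
            for v in truth:
                regime = regimes[v.key]
                p_fn = cfg.p_fn_low if regime == "low" else cfg.p_fn_high
                if rng.random() < p_fn:
                    fn_ledger.append({"key": list(v.key), "regime": regime,
                                      "variant_class": v.variant_class})
                else:
                    sample_calls.append(_call_metadata(rng, v, track))
            n_fp = int(rng.poisson(cfg.p_fp_snv))
            for _ in range(n_fp):
                fp = _fp_snv(cfg, rng, synref, panel_positions, taken)
                if fp is None:
                    continue
                fp = _call_metadata_fp(rng, fp, track)
                sample_calls.append(fp)
                fp_ledger.append({"key": list(fp.key), "variant_class": fp.variant_class,
                                  "regime": _regime_of(cfg, fp, low_windows)})
            if rng.random() < cfg.p_fp_indel_polyt:
                fp = _call_metadata_fp(rng, _fp_polyt_indel(cfg, synref), track)
                sample_calls.append(fp)
                fp_ledger.append({"key": list(fp.key), "variant_class": fp.variant_class,
                                  "regime": _regime_of(cfg, fp, low_windows)})
            sample_calls.sort(key=lambda v: v.key)
            calls[sid] = sample_calls
            fp_keys = {tuple(d["key"]) for d in fp_ledger}
            emitted[sid] = [
                denormalize(v, synref.references[v.contig], rng) if v.key in fp_keys else v
                for v in sample_calls
            ]
            sample_ledgers[sid] = {"fn": fn_ledger, "fp": fp_ledger}

    threshold = cfg.low_depth_cap
    pair_ledgers = []
    for pair_id, sid_a, sid_b in pair_ids:
        a_keys = {v.key: v for v in calls[sid_a]}
        b_keys = {v.key: v for v in calls[sid_b]}
        discordant = []
        for key in sorted(set(a_keys) ^ set(b_keys)):
            v = a_keys.get(key) or b_keys[key]
            contig, pos1 = key[0], key[1]
            da = depths[sid_a].depth(contig, pos1 - 1)
            db = depths[sid_b].depth(contig, pos1 - 1)
            discordant.append({
                "key": list(key),
                "direction": "only_in_A" if key in a_keys else "only_in_B",
                "variant_class": v.variant_class,
                "stratum": "low" if min(da, db) <= threshold else "high",
            })
        pair_ledgers.append({
            "pair_id": pair_id, "sample_a": sid_a, "sample_b": sid_b,
            "discordant": discordant,
        })

    ledger = GroundTruthLedger(
        truth_keys=[list(v.key) for v in truth],
        samples=sample_ledgers,
        pairs=pair_ledgers,
        low_coverage_windows=[
            [c, w * cfg.depth_window, (w + 1) * cfg.depth_window]
            for c, w in sorted(low_windows)
        ],
        stratum_threshold=threshold,
    )
    return SyntheticCohort(
        config=cfg, reference=synref, panel=panel, truth=truth,
        calls=calls, emitted_calls=emitted, depths=depths,
        ledger=ledger, pair_ids=pair_ids,
    )


def _regime_of(
    cfg: SimulationConfig, v: VariantRecord, low_windows: set[tuple[str, int]]
) -> str:
    return "low" if (v.contig, (v.pos - 1) // cfg.depth_window) in low_windows else "high"


def _call_metadata_fp(
    rng: np.random.Generator, v: VariantRecord, track: CoverageTrack
) -> VariantRecord:
    dp = max(track.depth(v.contig, v.pos - 1), 10)
    fwd = int(rng.binomial(dp, 0.5))
    return replace(v, depth=dp, depth_per_strand=(fwd, dp - fwd),
                   strand_bias=round(float(rng.uniform(0.0, 0.05)), 4))


def simulate_cohort(cfg: SimulationConfig | None = None) -> SyntheticCohort:
    """One-call generation: reference, panel, truth, paired call sets, depth
    tracks and ledger."""
    cfg = cfg or SimulationConfig()
    synref = make_reference(cfg)
    panel = build_panel(synref.exons, cfg.panel_padding, name="synthetic_panel")
    return make_truth_and_calls(cfg, synref, panel)


def make_qc_cohort(
    panel: PanelDefinition,
    cumulative_counts: tuple[int, int, int] = (225, 264, 281),
    n_samples: int = 288,
    depth_threshold: int = 50,
    tier_cutoffs: tuple[float, float, float] = (0.90, 0.97, 0.995),
    seed: int = 0,
) -> list[CoverageTrack]:
    """Depth tracks for a QC run with prescribed cumulative tier membership.

    ``cumulative_counts`` = (n at >=99.5%, n at >=97%, n at >=90%); the
    remaining samples fall below the failure cutoff. Counts are satisfied
    exactly by construction.
    """
    c995, c97, c90 = cumulative_counts
    if not (0 <= c995 <= c97 <= c90 <= n_samples):
        raise ConfigError("cumulative counts must be nested and within n_samples")
    if n_samples <= 0:
        raise ConfigError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    total = panel.total_bases
    a, b, c = tier_cutoffs
    k_a, k_b, k_c = (math.ceil(x * total) for x in (a, b, c))
    # exclusive tier sizes, best to worst
    tier_k_ranges = (
        [(k_c, total)] * c995
        + [(k_b, k_c - 1)] * (c97 - c995)
        + [(k_a, k_b - 1)] * (c90 - c97)
        + [(total // 2, k_a - 1)] * (n_samples - c90)
    )
    contig_sizes: dict[str, int] = {}
    for iv in panel.intervals:
        contig_sizes[iv.contig] = max(contig_sizes.get(iv.contig, 0), iv.end)
    tracks = []
    for s, (k_lo, k_hi) in enumerate(tier_k_ranges):
        k = int(rng.integers(k_lo, k_hi + 1))
        vals = np.empty(total, dtype=np.int64)
        perm = rng.permutation(total)
        vals[perm[:k]] = rng.integers(depth_threshold, depth_threshold + 400, size=k)
        vals[perm[k:]] = rng.integers(0, depth_threshold, size=total - k)
        arrays = {ctg: np.zeros(size, dtype=np.int64) for ctg, size in contig_sizes.items()}
        offset = 0
        for iv in panel.intervals:
            arrays[iv.contig][iv.start : iv.end] = vals[offset : offset + iv.length]
            offset += iv.length
        tracks.append(CoverageTrack(f"qc_sample_{s + 1:03d}", arrays))
    return tracks


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Emit the cohort to disk: FASTA reference, panel BED, truth VCF,
    per-sample call VCFs and depth TSVs, ledger JSON, and a pair manifest."""
    outdir = Path(outdir)
    (outdir / "calls").mkdir(parents=True, exist_ok=True)
    (outdir / "depth").mkdir(parents=True, exist_ok=True)
    vcfio.write_fasta(cohort.reference.references, outdir / "reference.fasta")
    from .panel import write_bed

    write_bed(cohort.panel, outdir / "panel.bed")
    contigs = vcfio.contig_lengths(cohort.reference.references)
    vcfio.write_vcf(cohort.truth, outdir / "truth.vcf", contigs, sample_id="TRUTH")
    for sid, records in cohort.emitted_calls.items():
        vcfio.write_vcf(records, outdir / "calls" / f"{sid}.vcf", contigs, sample_id=sid)
    for sid, track in cohort.depths.items():
        track.to_tsv(outdir / "depth" / f"{sid}.depth.tsv", panel=cohort.panel)
    (outdir / "ledger.json").write_text(cohort.ledger.to_json())
    manifest = [
        {"pair_id": p, "sample_a": a, "sample_b": b} for p, a, b in cohort.pair_ids
    ]
    (outdir / "pairs.json").write_text(json.dumps(manifest, indent=1))
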
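"""Per-base coverage tracks and sample-level coverage QC.

Sequencing quality per sample is summarised as the fraction of panel bases
reaching a depth threshold (50x by default) and classified into tiers:
below 90% the sample failed; 90-97% it may have gaps; 97-99.5% it has at most
minor gaps; at or above 99.5% substantial gaps are unlikely. Boundary values
belong to the better tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataIntegrityError, PreconditionError
from .panel import GenomicInterval, PanelDefinition

TIER_FAIL = "fail"
TIER_MAY_HAVE_GAPS = "may_have_gaps"
TIER_MINOR_GAPS = "minor_gaps"
TIER_PASS_CLEAN = "pass_clean"

#: tiers ordered worst to best
TIERS = (TIER_FAIL, TIER_MAY_HAVE_GAPS, TIER_MINOR_GAPS, TIER_PASS_CLEAN)


class CoverageTrack:
    """Per-base read depth for one sample, stored as one array per contig.

    Positions are 0-based; positions absent from the table are depth 0.
    """

    def __init__(self, sample_id: str, depths: dict[str, np.ndarray]):
        self.sample_id = sample_id
        self._depths = {c: np.asarray(d, dtype=np.int64) for c, d in depths.items()}
        for c, d in self._depths.items():
            if d.ndim != 1 or (d.size and d.min() < 0):
                raise DataIntegrityError(f"invalid depth array for contig {c!r}")

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._depths)

    def array(self, contig: str) -> np.ndarray:
        if contig not in self._depths:
            raise DataIntegrityError(f"no depth data for contig {contig!r} in sample {self.sample_id!r}")
        return self._depths[contig]

    def depth(self, contig: str, pos0: int, strict: bool = False) -> int:
        """Depth at a 0-based position; 0 for positions beyond the table.

        With ``strict`` an unknown contig raises a data-integrity error,
        which is what call-site lookups want.
        """
        arr = self._depths.get(contig)
        if arr is None:
            if strict:
                raise DataIntegrityError(
                    f"missing depth for contig {contig!r} in sample {self.sample_id!r}"
                )
            return 0
        if pos0 < 0:
            raise DataIntegrityError(f"negative position {pos0}")
        return int(arr[pos0]) if pos0 < arr.size else 0

    def to_dataframe(self, panel: PanelDefinition | None = None) -> pd.DataFrame:
        """Long-format table (chrom, pos, depth, sample_id), optionally
        restricted to panel positions."""
        rows = []
        if panel is not None:
            for iv in panel.intervals:
                arr = self._depths.get(iv.contig)
                pos = np.arange(iv.start, iv.end)
                dep = (
                    arr[iv.start : iv.end]
                    if arr is not None and arr.size >= iv.end
                    else np.array([self.depth(iv.contig, p) for p in pos])
                )
                rows.append(pd.DataFrame({"chrom": iv.contig, "pos": pos, "depth": dep}))
        else:
            for c, arr in self._depths.items():
                rows.append(pd.DataFrame({"chrom": c, "pos": np.arange(arr.size), "depth": arr}))
        df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "pos", "depth"]
        )
        df["sample_id"] = self.sample_id
        return df

    def to_tsv(self, path: str | Path, panel: PanelDefinition | None = None) -> None:
        self.to_dataframe(panel).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sample_id: str | None = None) -> "CoverageTrack":
        required = {"chrom", "pos", "depth"}
        if not required <= set(df.columns):
            raise DataIntegrityError(f"depth table must have columns {sorted(required)}")
        if sample_id is None:
            ids = df["sample_id"].unique() if "sample_id" in df.columns else []
            if len(ids) != 1:
                raise DataIntegrityError("depth table must contain exactly one sample_id")
            sample_id = str(ids[0])
        elif "sample_id" in df.columns:
            df = df[df["sample_id"] == sample_id]
        depths: dict[str, np.ndarray] = {}
        for contig, grp in df.groupby("chrom", sort=False):
            size = int(grp["pos"].max()) + 1
            arr = np.zeros(size, dtype=np.int64)
            arr[grp["pos"].to_numpy()] = grp["depth"].to_numpy()
            depths[str(contig)] = arr
        return cls(sample_id, depths)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "CoverageTrack":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), sample_id=sample_id)


@dataclass(frozen=True)
class QCPolicy:
    """Depth threshold and tier cutoffs (fractions of panel bases)."""

    depth_threshold: int = 50
    tier_cutoffs: tuple[float, float, float] = (0.90, 0.97, 0.995)

    def __post_init__(self) -> None:
        a, b, c = self.tier_cutoffs
        if not (0 < a < b < c < 1):
            raise ConfigError("tier cutoffs must be strictly increasing and in (0, 1)")
        if self.depth_threshold <= 0:
            raise ConfigError("depth threshold must be positive")


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    pct_bases_at_depth: float
    tier: str


def classify_tier(pct: float, policy: QCPolicy) -> str:
    """Tier for a percent-of-bases value; boundaries go to the better tier."""
    a, b, c = (100.0 * x for x in policy.tier_cutoffs)
    if pct >= c:
        return TIER_PASS_CLEAN
    if pct >= b:
        return TIER_MINOR_GAPS
    if pct >= a:
        return TIER_MAY_HAVE_GAPS
    return TIER_FAIL


def sample_qc(track: CoverageTrack, panel: PanelDefinition, policy: QCPolicy | None = None) -> SampleQC:
    """Fraction of panel bases at or above the depth threshold, tiered."""
    policy = policy or QCPolicy()
    total = panel.total_bases
    if total == 0:
        raise PreconditionError("panel is empty")
    covered = 0
    for iv in panel.intervals:
        arr = track._depths.get(iv.contig)
        if arr is None:
            continue
        seg = arr[iv.start : min(iv.end, arr.size)]
        covered += int((seg >= policy.depth_threshold).sum())
    pct = 100.0 * covered / total
    return SampleQC(sample_id=track.sample_id, pct_bases_at_depth=pct, tier=classify_tier(pct, policy))


def region_mean_coverage(track: CoverageTrack, region: GenomicInterval) -> float:
    """Arithmetic mean depth over a region (positions past the table are 0)."""
    if region.length == 0:
        raise PreconditionError("empty region")
    return float(np.mean([track.depth(region.contig, p) for p in range(region.start, region.end)]))


def run_summary(samples: Sequence[SampleQC], policy: QCPolicy | None = None) -> dict:
    """Run-level QC: cumulative proportion of samples at or above each cutoff,
    plus exclusive per-tier counts."""
    if not samples:
        raise PreconditionError("run_summary needs at least one sample")
    policy = policy or QCPolicy()
    n = len(samples)
    pcts = np.array([s.pct_bases_at_depth for s in samples])
    cumulative = {}
    for cutoff in policy.tier_cutoffs:
        count = int((pcts >= 100.0 * cutoff).sum())
        cumulative[f">={100 * cutoff:g}%"] = {
            "count": count,
            "proportion_pct": 100.0 * count / n,
        }
    tier_counts = {tier: sum(1 for s in samples if s.tier == tier) for tier in TIERS}
    return {"n_samples": n, "cumulative": cumulative, "tier_counts": tier_counts}
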
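"""YAML configuration for the CLI: paths, thresholds and model parameters.

The file is a flat document with one section per stage; every section is
optional and falls back to the documented defaults. Round-trips losslessly
through :func:`load_config` / :func:`dump_config`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .concordance import ConcordancePolicy
from .coverage import QCPolicy
from .errors import ConfigError
from .filtering import FilterThresholds
from .ops import CostItem, CostParams, OpsParams, StageSchedule, default_schedule


@dataclass
class PipelineConfig:
    reference_fasta: str = ""
    panel_bed: str = ""
    query_vcf: str = ""
    truth_vcf: str = ""
    pairs_manifest: str = ""  # JSON list of pair dicts (see simulate.write_cohort)
    depth_dir: str = ""
    out_dir: str = "results"
    seed: int = 0
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    concordance: ConcordancePolicy = field(default_factory=ConcordancePolicy)
    qc: QCPolicy = field(default_factory=QCPolicy)
    ops: OpsParams = field(default_factory=OpsParams)
    schedule: StageSchedule = field(default_factory=default_schedule)
    costs: CostParams = field(default_factory=CostParams)


def load_config(path: str | Path) -> PipelineConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    cfg = PipelineConfig()
    simple = {
        "reference_fasta", "panel_bed", "query_vcf", "truth_vcf",
        "pairs_manifest", "depth_dir", "out_dir", "seed",
    }
    for key, value in doc.items():
        if key in simple:
            setattr(cfg, key, value)
        elif key == "thresholds":
            cfg.thresholds = FilterThresholds(**value)
        elif key == "concordance":
            cfg.concordance = ConcordancePolicy(**value)
        elif key == "qc":
            value = dict(value)
            if "tier_cutoffs" in value:
                value["tier_cutoffs"] = tuple(value["tier_cutoffs"])
            cfg.qc = QCPolicy(**value)
        elif key == "ops":
            cfg.ops = OpsParams(**value)
        elif key == "schedule":
            cfg.schedule = StageSchedule(stages=tuple((s, int(d)) for s, d in value))
        elif key == "costs":
            items = tuple(CostItem(**item) for item in value.get("items", []))
            cfg.costs = CostParams(items=items, include_labour=value.get("include_labour", True))
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return cfg


def dump_config(cfg: PipelineConfig) -> str:
    doc = {
        "reference_fasta": cfg.reference_fasta,
        "panel_bed": cfg.panel_bed,
        "query_vcf": cfg.query_vcf,
        "truth_vcf": cfg.truth_vcf,
        "pairs_manifest": cfg.pairs_manifest,
        "depth_dir": cfg.depth_dir,
        "out_dir": cfg.out_dir,
        "seed": cfg.seed,
        "thresholds": asdict(cfg.thresholds),
        "concordance": asdict(cfg.concordance),
        "qc": {"depth_threshold": cfg.qc.depth_threshold, "tier_cutoffs": list(cfg.qc.tier_cutoffs)},
        "ops": asdict(cfg.ops),
        "schedule": [[s, d] for s, d in cfg.schedule.stages],
        "costs": {
            "include_labour": cfg.costs.include_labour,
            "items": [asdict(i) for i in cfg.costs.items],
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
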
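"""Deterministic laboratory operations model: turnaround, throughput, cost.

Models a screening laboratory running a fixed multi-day stage schedule
(sample booking through reporting), daily sequencer batches, and a per-sample
cost built from user-supplied itemized components. The arithmetic is simple
by design: turnaround time is the span of the schedule in days; a repeat test
is two full sequential cycles; weekly throughput is batch size x runs/day x
days/week x sequencers, deflated by the repeat rate for unique samples; and
the repeat rate inflates repeat-sensitive cost items by 1/(1 - r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class StageSchedule:
    """Ordered (stage name, day index) assignments; day indices start at 1
    and must be non-decreasing along the stage order."""

    stages: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ConfigError("schedule must contain at least one stage")
        days = [d for _, d in self.stages]
        if min(days) < 1:
            raise ConfigError("day indices start at 1")
        if any(b < a for a, b in zip(days, days[1:])):
            raise ConfigError("day indices must be non-decreasing along the stage order")


def default_schedule() -> StageSchedule:
    """The four-day screening workflow: wet-lab start on day 1, library
    finishing and chip loading day 2, sequencing day 3, analysis and
    reporting day 4."""
    return StageSchedule(
        stages=(
            ("booking_on", 1),
            ("dbs_punching", 1),
            ("dna_extraction", 1),
            ("library_prep_start", 1),
            ("digestion", 2),
            ("barcode_ligation", 2),
            ("library_qc", 2),
            ("pooling", 2),
            ("chip_loading", 2),
            ("sequencing", 3),
            ("data_processing", 3),
            ("analysis", 4),
            ("reporting", 4),
        )
    )


@dataclass(frozen=True)
class OpsParams:
    """Batching parameters for throughput. Defaults model two 96-sample
    chip runs set up daily in a seven-day service with a 3/96 repeat rate."""

    samples_per_run: int = 96
    runs_per_day: int = 2
    days_per_week: int = 7
    repeat_rate: float = 3 / 96
    sequencers: int = 1

    def __post_init__(self) -> None:
        if min(self.samples_per_run, self.runs_per_day, self.days_per_week, self.sequencers) <= 0:
            raise ConfigError("batch parameters must be positive")
        if not 0 <= self.repeat_rate < 1:
            raise ConfigError("repeat_rate must lie in [0, 1)")


@dataclass(frozen=True)
class CostItem:
    name: str
    amount: float
    is_labour: bool = False
    repeat_sensitive: bool = True

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ConfigError("cost amounts must be non-negative")


@dataclass(frozen=True)
class CostParams:
    """Itemized per-sample costs. The itemization is user-supplied; the model
    only guarantees the aggregation arithmetic."""

    items: tuple[CostItem, ...] = ()
    include_labour: bool = True


def turnaround_days(schedule: StageSchedule) -> int:
    """Elapsed days from first to last scheduled stage, inclusive."""
    days = [d for _, d in schedule.stages]
    return max(days) - min(days) + 1


def repeat_turnaround_days(schedule: StageSchedule) -> int:
    """Turnaround for a sample needing a repeat: two sequential full cycles."""
    return 2 * turnaround_days(schedule)


def daily_library_capacity(params: OpsParams) -> int:
    """Libraries that can be prepared per day (batch size x runs/day)."""
    return params.samples_per_run * params.runs_per_day


def weekly_throughput(params: OpsParams) -> tuple[int, int]:
    """(gross, net_unique) samples per week.

    Gross counts every library sequenced; net deflates by the repeat rate to
    count unique samples resolved.
    """
    gross = params.samples_per_run * params.runs_per_day * params.days_per_week * params.sequencers
    net_unique = math.floor(gross * (1 - params.repeat_rate))
    return gross, net_unique


def cost_per_sample(costs: CostParams, params: OpsParams) -> float:
    """Aggregate itemized costs, inflating repeat-sensitive items by
    1/(1 - repeat_rate); labour items are dropped when ``include_labour``
    is off."""
    inflation = 1.0 / (1.0 - params.repeat_rate)
    total = 0.0
    for item in costs.items:
        if item.is_labour and not costs.include_labour:
            continue
        total += item.amount * (inflation if item.repeat_sensitive else 1.0)
    return total


def ops_report(
    schedule: StageSchedule | None = None,
    params: OpsParams | None = None,
    costs: CostParams | None = None,
) -> dict:
    """Combined operations summary used by the CLI and examples."""
    schedule = schedule or default_schedule()
    params = params or OpsParams()
    gross, net = weekly_throughput(params)
    report = {
        "schema_version": 1,
        "turnaround_days": turnaround_days(schedule),
        "repeat_turnaround_days": repeat_turnaround_days(schedule),
        "daily_library_capacity": daily_library_capacity(params),
        "weekly_throughput_gross": gross,
        "weekly_throughput_net_unique": net,
    }
    if costs is not None:
        report["cost_per_sample"] = round(cost_per_sample(costs, params), 2)
        costs_no_labour = CostParams(items=costs.items, include_labour=False)
        report["cost_per_sample_excl_labour"] = round(cost_per_sample(costs_no_labour, params), 2)
    return report
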
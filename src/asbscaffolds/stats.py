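"""Target annotation and summary statistics for series and scaffolds.

Reports the composition of the extracted analog series in the layout used
for large-scale scaffold surveys: counts and percentages of series per
category (single-site first-generation, single-site second-generation-only,
multi-site), series sizes, substitution sites, target counts, and the
single-/multi-target breakdown.  Percentages of series are computed against
the number of series; percentages of compounds against the number of
compounds participating in series (not all input compounds).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .scaffolds import STATUS_OK, ScaffoldResult
from .series import AnalogSeries

CATEGORIES = ("single_site_first", "single_site_second", "multi_site")


def round1(value: float) -> float:
    """Round to one decimal, half-up (presentation convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int) -> float:
    return round1(100.0 * numerator / denominator) if denominator else 0.0


def annotate_series(
    series: AnalogSeries, activity: Mapping[str, set[str]]
) -> tuple[frozenset[str], str | None]:
    """Union the member target annotations of a series.

    Returns the target set and a flag: "single" for exactly one target,
    "multi" for several, None for an unannotated series.  The series
    scaffold inherits this target set, so multi-target activity is captured
    at the scaffold level.
    """
    targets: set[str] = set()
    for member in series.members:
        targets |= set(activity.get(member, ()))
    if not targets:
        return frozenset(), None
    return frozenset(targets), "single" if len(targets) == 1 else "multi"


@dataclass
class CategoryStats:
    n_series: int = 0
    pct_series: float = 0.0
    n_compounds: int = 0
    pct_compounds: float = 0.0
    size_min: int = 0
    size_max: int = 0
    mean_size: float = 0.0
    mean_sites: float = 0.0
    n_single_target: int = 0
    n_multi_target: int = 0
    n_targets: int = 0


@dataclass
class StatsReport:
    """Summary of one extraction run (deterministic for fixed inputs)."""

    n_input_compounds: int = 0
    n_series: int = 0
    n_compounds_in_series: int = 0
    n_singletons: int = 0
    size_min: int = 0
    size_max: int = 0
    mean_size: float = 0.0
    mean_sites: float = 0.0
    n_targets: int = 0
    n_single_target_series: int = 0
    n_multi_target_series: int = 0
    n_scaffolds: int = 0
    n_scaffolds_first: int = 0
    n_scaffolds_second: int = 0
    n_compounds_covered: int = 0
    pct_series_covered: float = 0.0
    pct_compounds_covered: float = 0.0
    exclusions: dict[str, int] = field(default_factory=dict)
    categories: dict[str, CategoryStats] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "StatsReport":
        data = dict(data)
        data["categories"] = {
            k: CategoryStats(**v) for k, v in data.get("categories", {}).items()
        }
        return cls(**data)


def _mean(values: Iterable[float]) -> float:
    values = list(values)
    return round1(sum(values) / len(values)) if values else 0.0


def summarize(
    series_list: list[AnalogSeries],
    results: list[ScaffoldResult],
    activity: Mapping[str, set[str]] | None,
    n_input_compounds: int,
) -> StatsReport:
    """Compute the full report from one run's series and scaffold results."""
    activity = activity or {}
    by_id = {r.series_id: r for r in results}
    report = StatsReport(n_input_compounds=n_input_compounds)
    report.n_series = len(series_list)
    sizes = [len(s.members) for s in series_list]
    report.n_compounds_in_series = sum(sizes)
    report.n_singletons = n_input_compounds - report.n_compounds_in_series
    if sizes:
        report.size_min, report.size_max = min(sizes), max(sizes)
        report.mean_size = _mean(sizes)

    all_targets: set[str] = set()
    per_category: dict[str, list[AnalogSeries]] = {c: [] for c in CATEGORIES}
    category_sites: dict[str, list[int]] = {c: [] for c in CATEGORIES}
    category_targets: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    covered_sites: list[int] = []

    for series in series_list:
        targets, flag = annotate_series(series, activity)
        all_targets |= targets
        if flag == "single":
            report.n_single_target_series += 1
        elif flag == "multi":
            report.n_multi_target_series += 1
        result = by_id.get(series.id)
        if result is None or result.status != STATUS_OK or result.scaffold is None:
            reason = result.status if result else "missing"
            report.exclusions[reason] = report.exclusions.get(reason, 0) + 1
            continue
        scaffold = result.scaffold
        scaffold.targets = tuple(sorted(targets))
        report.n_scaffolds += 1
        if scaffold.generation == "first":
            report.n_scaffolds_first += 1
        else:
            report.n_scaffolds_second += 1
        report.n_compounds_covered += len(series.members)
        covered_sites.append(scaffold.n_sites)
        if scaffold.n_sites >= 2:
            cat = "multi_site"
        elif scaffold.generation == "first":
            cat = "single_site_first"
        else:
            cat = "single_site_second"
        per_category[cat].append(series)
        category_sites[cat].append(scaffold.n_sites)
        category_targets[cat] |= targets

    report.n_targets = len(all_targets)
    report.mean_sites = _mean(covered_sites)
    report.pct_series_covered = pct(report.n_scaffolds, report.n_series)
    report.pct_compounds_covered = pct(report.n_compounds_covered, report.n_compounds_in_series)

    for cat in CATEGORIES:
        group = per_category[cat]
        stats = CategoryStats()
        stats.n_series = len(group)
        stats.pct_series = pct(len(group), report.n_series)
        group_sizes = [len(s.members) for s in group]
        stats.n_compounds = sum(group_sizes)
        stats.pct_compounds = pct(stats.n_compounds, report.n_compounds_in_series)
        if group_sizes:
            stats.size_min, stats.size_max = min(group_sizes), max(group_sizes)
            stats.mean_size = _mean(group_sizes)
        stats.mean_sites = _mean(category_sites[cat])
        for s in group:
            _, flag = annotate_series(s, activity)
            if flag == "single":
                stats.n_single_target += 1
            elif flag == "multi":
                stats.n_multi_target += 1
        stats.n_targets = len(category_targets[cat])
        report.categories[cat] = stats
    return report


_LABELS = {
    "single_site_first": "Single site (first/second)",
    "single_site_second": "Single site (second only)",
    "multi_site": "Multiple sites (second)",
}


def render_table(report: StatsReport) -> str:
    """Human-readable summary table."""
    lines = [
        f"Compounds (input / in series / singletons): "
        f"{report.n_input_compounds} / {report.n_compounds_in_series} / {report.n_singletons}",
        f"Analog series: {report.n_series}  "
        f"(size {report.size_min}-{report.size_max}, mean {report.mean_size})",
        f"Targets: {report.n_targets}  "
        f"(single-target series {report.n_single_target_series}, "
        f"multi-target {report.n_multi_target_series})",
        f"ASB scaffolds: {report.n_scaffolds}  "
        f"(first generation {report.n_scaffolds_first}, second {report.n_scaffolds_second})",
        f"Coverage: {report.pct_series_covered}% of series, "
        f"{report.pct_compounds_covered}% of compounds in series",
    ]
    for reason, count in sorted(report.exclusions.items()):
        lines.append(f"Excluded series ({reason}): {count}")
    for cat in CATEGORIES:
        stats = report.categories.get(cat)
        if stats is None:
            continue
        lines.append(
            f"{_LABELS[cat]}: {stats.n_series} series ({stats.pct_series}%), "
            f"{stats.n_compounds} compounds ({stats.pct_compounds}%), "
            f"mean size {stats.mean_size}, mean sites {stats.mean_sites}, "
            f"targets {stats.n_targets}"
        )
    return "\n".join(lines)
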
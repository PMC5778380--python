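"""End-to-end pipeline: fragment → series → scaffolds → stats.

Pure functions over in-memory objects plus a configured artifact-writing
runner used by the command line.  Two runs on identical inputs and
configuration produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io
from .chem import Molecule, merge_duplicates
from .recap import RULE_IDS, SizeRestrictionConfig
from .scaffolds import (
    STATUS_OK,
    RGroupTable,
    ScaffoldResult,
    build_rgroup_table,
    derive_scaffold,
)
from .series import SeriesExtraction, decompose_mms, extract_from_molecules
from .stats import StatsReport, summarize

logger = logging.getLogger("asbscaffolds")


@dataclass
class RunConfig:
    """Serializable run configuration, echoed into every artifact header."""

    smiles_path: str = ""
    activity_path: str | None = None
    out_dir: str = "asb_out"
    keep_stereo: bool = True
    recap_rules: tuple[str, ...] = RULE_IDS
    size: SizeRestrictionConfig = field(default_factory=SizeRestrictionConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        data = asdict(self)
        data["recap_rules"] = list(self.recap_rules)
        return data

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        size = SizeRestrictionConfig(
            core_to_sub_ratio=float(data.pop("core_to_sub_ratio", 2.0)),
            max_sub_heavy=int(data.pop("max_sub_heavy", 13)),
            max_diff_heavy=int(data.pop("max_diff_heavy", 8)),
        )
        rules = tuple(data.pop("recap_rules", RULE_IDS))
        unknown = set(rules) - set(RULE_IDS)
        if unknown:
            raise ValueError(f"unknown recap rules in config: {sorted(unknown)}")
        cfg = cls(size=size, recap_rules=rules, **data)
        for key, value in overrides.items():
            setattr(cfg, key, value)
        return cfg


@dataclass
class PipelineResult:
    molecules: list[Molecule]
    extraction: SeriesExtraction
    results: list[ScaffoldResult]
    tables: list[RGroupTable]
    report: StatsReport
    n_raw: int = 0
    n_merged: int = 0


def run(
    molecules: list[Molecule],
    activity: dict[str, set[str]] | None = None,
    size: SizeRestrictionConfig | None = None,
    rules: tuple[str, ...] | None = None,
) -> PipelineResult:
    """Run the full method on standardized molecules (in memory)."""
    n_raw = len(molecules)
    molecules = merge_duplicates(molecules)
    n_merged = n_raw - len(molecules)
    logger.info("molecules: %d read, %d merged duplicates", n_raw, n_merged)
    extraction = extract_from_molecules(molecules, size, rules)
    logger.info(
        "RMMPs: %d; series: %d; singletons: %d",
        len(extraction.rmmps),
        len(extraction.series),
        len(extraction.singletons),
    )
    molmap = {m.id: m for m in molecules}
    results: list[ScaffoldResult] = []
    tables: list[RGroupTable] = []
    for series in extraction.series:
        result = derive_scaffold(series, molmap)
        results.append(result)
        if result.status == STATUS_OK and result.scaffold is not None:
            tables.append(build_rgroup_table(series, result.scaffold, molmap))
    report = summarize(extraction.series, results, activity, len(molecules))
    by_gen = (report.n_scaffolds_first, report.n_scaffolds_second)
    logger.info(
        "scaffolds: %d (first %d, second %d); exclusions: %s",
        report.n_scaffolds,
        *by_gen,
        dict(sorted(report.exclusions.items())) or "none",
    )
    return PipelineResult(molecules, extraction, results, tables, report, n_raw, n_merged)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Read inputs per the configuration, run, and write all artifacts."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    molecules = io.read_smiles(cfg.smiles_path, keep_stereo=cfg.keep_stereo)
    activity = None
    if cfg.activity_path:
        rows = io.read_activity(cfg.activity_path)
        activity, unknown = io.activity_lookup(rows, {m.id for m in merge_duplicates(molecules)})
        if unknown:
            logger.warning("activity rows for %d unknown compound ids skipped", len(unknown))
    result = run(molecules, activity, cfg.size, cfg.recap_rules)
    provenance = cfg.to_dict()

    io.write_fragments_tsv(out_dir / "frags.tsv", result.extraction.records, provenance)
    io.write_edges_tsv(out_dir / "edges.tsv", result.extraction.rmmps, provenance)
    mms_by_series = {s.id: decompose_mms(s) for s in result.extraction.series}
    series_doc = io.series_to_json(
        result.extraction.series,
        mms_by_series,
        result.extraction.singletons,
        result.molecules,
        provenance,
    )
    (out_dir / "series.json").write_text(json.dumps(series_doc, indent=1, sort_keys=True))
    member_counts = {s.id: len(s.members) for s in result.extraction.series}
    io.write_scaffolds_tsv(out_dir / "scaffolds.tsv", result.results, member_counts, provenance)
    io.write_rgroup_tables(out_dir / "rgroups", result.tables, provenance)
    report_doc = {"config": provenance, "report": result.report.to_dict()}
    (out_dir / "report.json").write_text(json.dumps(report_doc, indent=1, sort_keys=True))
    return result
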
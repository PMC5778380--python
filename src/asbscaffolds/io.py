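"""File formats: SMILES lists, activity CSV, and the pipeline artifacts.

Text formats only.  TSV artifacts start with a ``#``-prefixed provenance
line echoing the run configuration; readers skip ``#`` lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .chem import Fragment, Molecule, ParseError, standardize
from .recap import FragmentationRecord
from .scaffolds import ASBScaffold, RGroupTable, ScaffoldResult
from .series import MMS, RMMP, AnalogSeries


def read_smiles(path: str | Path, keep_stereo: bool = True) -> list[Molecule]:
    """Read a .smi file: structure, whitespace, identifier; '#' comments."""
    molecules: list[Molecule] = []
    seen_ids: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'SMILES identifier': {text!r}")
        raw, mol_id = parts
        mol_id = mol_id.strip()
        if mol_id in seen_ids:
            raise ParseError(f"{path}:{lineno}: duplicate identifier {mol_id!r}")
        seen_ids.add(mol_id)
        try:
            structure = standardize(raw, keep_stereo, context=f"{path}:{lineno} id={mol_id}")
        except ParseError:
            raise
        molecules.append(Molecule(id=mol_id, structure=structure))
    return molecules


def write_smiles(path: str | Path, molecules: Iterable[Molecule]) -> None:
    lines = [f"{m.structure}\t{m.id}" for m in molecules]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_activity(path: str | Path) -> list[tuple[str, str]]:
    """Activity CSV with header ``compound_id,target_id``; one pair per row."""
    frame = pd.read_csv(path, dtype=str, comment="#")
    expected = ["compound_id", "target_id"]
    if list(frame.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, found {list(frame.columns)}")
    return [(str(r.compound_id), str(r.target_id)) for r in frame.itertuples()]


def write_activity(path: str | Path, rows: Iterable[tuple[str, str]]) -> None:
    frame = pd.DataFrame(sorted(rows), columns=["compound_id", "target_id"])
    frame.to_csv(path, index=False)


def activity_lookup(
    rows: Iterable[tuple[str, str]], known_ids: set[str]
) -> tuple[dict[str, set[str]], list[str]]:
    """Target sets per known compound; unknown compound ids are returned
    separately for logging and skipped."""
    mapping: dict[str, set[str]] = {}
    unknown: list[str] = []
    for compound_id, target_id in rows:
        if compound_id in known_ids:
            mapping.setdefault(compound_id, set()).add(target_id)
        else:
            unknown.append(compound_id)
    return mapping, sorted(set(unknown))


def _provenance(config: Mapping | None) -> str:
    return "# config: " + json.dumps(config or {}, sort_keys=True) + "\n"


def write_fragments_tsv(
    path: str | Path, records: Iterable[FragmentationRecord], config: Mapping | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        fh.write("parent_id\trule_id\tcore\tsubstituent\n")
        for rec in records:
            fh.write(
                f"{rec.parent_id}\t{rec.rule_id}\t{rec.core.structure}\t"
                f"{rec.substituent.structure}\n"
            )


def write_edges_tsv(path: str | Path, rmmps: Iterable[RMMP], config: Mapping | None = None) -> None:
    """Two-column compound-id pair list (one row per pair), for graph tools."""
    seen: set[tuple[str, str]] = set()
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        fh.write("compound_a\tcompound_b\n")
        for rmmp in rmmps:
            pair = (rmmp.compound_a, rmmp.compound_b)
            if pair not in seen:
                seen.add(pair)
                fh.write(f"{pair[0]}\t{pair[1]}\n")


def series_to_json(
    series_list: list[AnalogSeries],
    mms_by_series: Mapping[str, list[MMS]],
    singletons: list[str],
    molecules: list[Molecule],
    config: Mapping | None = None,
) -> dict:
    return {
        "config": dict(config or {}),
        "molecules": {
            m.id: {"structure": m.structure, "aliases": list(m.aliases)} for m in molecules
        },
        "series": [
            {
                "id": s.id,
                "members": list(s.members),
                "cores": list(s.cores),
                "edges": [
                    {
                        "a": e.compound_a,
                        "b": e.compound_b,
                        "core": e.core.structure,
                        "sub_a": e.sub_a.structure,
                        "sub_b": e.sub_b.structure,
                    }
                    for e in s.edges
                ],
                "mms": [
                    {"core": m.core.structure, "members": dict(sorted(m.members.items()))}
                    for m in mms_by_series.get(s.id, [])
                ],
            }
            for s in series_list
        ],
        "singletons": list(singletons),
    }


def series_from_json(data: dict) -> tuple[list[AnalogSeries], list[str], dict[str, Molecule]]:
    molecules = {
        mol_id: Molecule(
            id=mol_id, structure=entry["structure"], aliases=tuple(entry.get("aliases", ()))
        )
        for mol_id, entry in data["molecules"].items()
    }
    series_list = []
    for s in data["series"]:
        edges = tuple(
            RMMP(
                compound_a=e["a"],
                compound_b=e["b"],
                core=Fragment.from_smiles(e["core"]),
                sub_a=Fragment.from_smiles(e["sub_a"]),
                sub_b=Fragment.from_smiles(e["sub_b"]),
            )
            for e in s["edges"]
        )
        series_list.append(
            AnalogSeries(
                id=s["id"], members=tuple(s["members"]), edges=edges, cores=tuple(s["cores"])
            )
        )
    return series_list, list(data.get("singletons", ())), molecules


def write_scaffolds_tsv(
    path: str | Path,
    results: Iterable[ScaffoldResult],
    member_counts: Mapping[str, int],
    config: Mapping | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        fh.write(
            "series_id\tscaffold\tn_sites\tgeneration\tmember_count\t"
            "n_targets\ttargets\tstatus\n"
        )
        for res in results:
            s = res.scaffold
            fh.write(
                "\t".join(
                    [
                        res.series_id,
                        s.structure if s else "",
                        str(s.n_sites) if s else "",
                        s.generation if s else "",
                        str(member_counts.get(res.series_id, s.member_count if s else 0)),
                        str(len(s.targets)) if s else "0",
                        ";".join(s.targets) if s else "",
                        res.status,
                    ]
                )
                + "\n"
            )


def read_scaffolds_tsv(path: str | Path) -> list[ScaffoldResult]:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    results = []
    for row in frame.itertuples():
        scaffold = None
        if row.scaffold:
            scaffold = ASBScaffold(
                structure=row.scaffold,
                n_sites=int(row.n_sites),
                generation=row.generation,
                series_id=row.series_id,
                member_count=int(row.member_count),
                targets=tuple(t for t in row.targets.split(";") if t),
            )
        results.append(ScaffoldResult(series_id=row.series_id, status=row.status, scaffold=scaffold))
    return results


def write_rgroup_tables(
    directory: str | Path, tables: Iterable[RGroupTable], config: Mapping | None = None
) -> None:
    """One TSV per series: member_id, R1..Rn."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for table in tables:
        n = table.scaffold.n_sites
        with open(directory / f"{table.scaffold.series_id}.tsv", "w") as fh:
            fh.write(_provenance(config))
            fh.write("# scaffold: " + table.scaffold.structure + "\n")
            fh.write("member_id\t" + "\t".join(f"R{k}" for k in range(1, n + 1)) + "\n")
            for member_id in sorted(table.rows):
                row = table.rows[member_id]
                fh.write(member_id + "\t" + "\t".join(row[k] for k in range(1, n + 1)) + "\n")
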
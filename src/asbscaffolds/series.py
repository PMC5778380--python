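"""RMMP enumeration, the compound network, and analog series extraction.

Fragmentations are indexed by their canonical core.  Two distinct compounds
that produce the same core with different substituents form a RECAP matched
molecular pair (RMMP), provided the exchange passes the size restrictions.
RMMPs are edges of a network over compounds; each connected component is an
analog series.  Within a series, the compounds sharing one core form a
matching molecular series (MMS) — a maximal single-site sub-series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .chem import Fragment, Molecule
from .recap import (
    FragmentationRecord,
    SizeRestrictionConfig,
    enumerate_cuts,
    passes_size_restriction,
)

# core structure -> parent id -> sorted substituent structures
CoreIndex = dict[str, dict[str, list[str]]]


@dataclass(frozen=True)
class RMMP:
    """A pair of compounds differing by one exchanged substituent pair."""

    compound_a: str
    compound_b: str
    core: Fragment
    sub_a: Fragment
    sub_b: Fragment


@dataclass
class AnalogSeries:
    """A connected component of the RMMP network (two or more compounds)."""

    id: str
    members: tuple[str, ...]
    edges: tuple[RMMP, ...]
    cores: tuple[str, ...]

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class MMS:
    """Maximal single-site sub-series: members sharing one exchange core."""

    core: Fragment
    members: dict[str, str]  # molecule id -> substituent structure


def index_cores(records: list[FragmentationRecord]) -> CoreIndex:
    """Group fragmentations by canonical core structure."""
    index: CoreIndex = {}
    for rec in records:
        per_parent = index.setdefault(rec.core.structure, {})
        subs = per_parent.setdefault(rec.parent_id, [])
        if rec.substituent.structure not in subs:
            subs.append(rec.substituent.structure)
            subs.sort()
    return index


def enumerate_rmmps(index: CoreIndex, cfg: SizeRestrictionConfig) -> list[RMMP]:
    """All RMMPs: one per unordered compound pair per shared core.

    Deterministic: sorted by core structure, then by the id pair.  If a pair
    admits several substituent combinations for one core (symmetric
    molecules), the lexicographically smallest qualifying combination is
    kept.
    """
    rmmps: list[RMMP] = []
    for core_structure in sorted(index):
        per_parent = index[core_structure]
        if len(per_parent) < 2:
            continue
        core = Fragment.from_smiles(core_structure)
        parents = sorted(per_parent)
        for i, id_a in enumerate(parents):
            for id_b in parents[i + 1 :]:
                best = None
                for sa in per_parent[id_a]:
                    for sb in per_parent[id_b]:
                        if sa == sb:
                            continue
                        frag_a, frag_b = Fragment.from_smiles(sa), Fragment.from_smiles(sb)
                        if not passes_size_restriction(core, frag_a, frag_b, cfg):
                            continue
                        if best is None or (sa, sb) < (best[0].structure, best[1].structure):
                            best = (frag_a, frag_b)
                if best is not None:
                    rmmps.append(RMMP(id_a, id_b, core, best[0], best[1]))
    return rmmps


def extract_series(rmmps: list[RMMP]) -> list[AnalogSeries]:
    """Disjoint clusters of the RMMP network, as analog series.

    Compounds with no RMMP belong to no series.  Series are ordered and
    numbered by their lexicographically smallest member.
    """
    graph = nx.Graph()
    edges_by_pair: dict[tuple[str, str], list[RMMP]] = {}
    for rmmp in rmmps:
        graph.add_edge(rmmp.compound_a, rmmp.compound_b)
        edges_by_pair.setdefault((rmmp.compound_a, rmmp.compound_b), []).append(rmmp)
    components = sorted(
        (tuple(sorted(comp)) for comp in nx.connected_components(graph)), key=lambda c: c[0]
    )
    series: list[AnalogSeries] = []
    for n, members in enumerate(components, start=1):
        member_set = set(members)
        edges = tuple(
            e
            for pair in sorted(edges_by_pair)
            if pair[0] in member_set
            for e in edges_by_pair[pair]
        )
        cores = tuple(sorted({e.core.structure for e in edges}))
        series.append(AnalogSeries(id=f"AS{n:04d}", members=members, edges=edges, cores=cores))
    return series


def decompose_mms(series: AnalogSeries) -> list[MMS]:
    """Split a series into its matching molecular series, one per shared core.

    For each core, compounds connected by RMMPs over that core are grouped;
    because the size restrictions compare the two exchanged substituents,
    pairwise qualification is not automatically transitive, so maximal
    cliques of the per-core pair graph are taken (almost always a single
    clique).  Every RMMP edge of the series is covered by at least one MMS.
    """
    per_core: dict[str, list[RMMP]] = {}
    for edge in series.edges:
        per_core.setdefault(edge.core.structure, []).append(edge)
    out: list[MMS] = []
    for core_structure in sorted(per_core):
        edges = per_core[core_structure]
        sub_of: dict[str, str] = {}
        graph = nx.Graph()
        for e in edges:
            graph.add_edge(e.compound_a, e.compound_b)
            sub_of[e.compound_a] = e.sub_a.structure
            sub_of[e.compound_b] = e.sub_b.structure
        cliques = sorted(
            (tuple(sorted(c)) for c in nx.find_cliques(graph) if len(c) >= 2),
        )
        core = Fragment.from_smiles(core_structure)
        for members in cliques:
            out.append(MMS(core=core, members={m: sub_of[m] for m in members}))
    return out


@dataclass
class SeriesExtraction:
    """Full stage-1 result: series plus the singleton audit list."""

    series: list[AnalogSeries]
    singletons: list[str]
    rmmps: list[RMMP]
    n_molecules: int = 0
    records: list[FragmentationRecord] = field(default_factory=list)


def extract_from_molecules(
    molecules: list[Molecule],
    cfg: SizeRestrictionConfig | None = None,
    rules: tuple[str, ...] | None = None,
) -> SeriesExtraction:
    """Run fragmentation → indexing → RMMP enumeration → clustering."""
    cfg = cfg or SizeRestrictionConfig()
    records: list[FragmentationRecord] = []
    for mol in molecules:
        records.extend(enumerate_cuts(mol, rules))
    rmmps = enumerate_rmmps(index_cores(records), cfg)
    series = extract_series(rmmps)
    in_series = {m for s in series for m in s.members}
    singletons = sorted(m.id for m in molecules if m.id not in in_series)
    return SeriesExtraction(
        series=series,
        singletons=singletons,
        rmmps=rmmps,
        n_molecules=len(molecules),
        records=records,
    )
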
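"""Analog series-based (ASB) scaffold derivation.

Every analog series is reduced to one scaffold — or excluded for a stated
reason — in two steps mirroring the two generations of the method:

* first generation: if the series has a single qualifying exchange core
  shared by all members, that core (one substitution site) is the scaffold;
* second generation: cores that are structural extensions of a smaller core
  at the same substitution site are redundant and removed; the substitution
  sites of the remaining nonredundant cores are transferred onto the
  analogs they match (shared analogs accumulate several sites), and the
  scaffold is the common remainder after cutting all marked site bonds.

A series whose sites cannot be mapped onto one remainder is excluded as
``ambiguous_mapping``; a series in which some member does not decompose as
scaffold + one substituent (or hydrogen) per site is excluded as
``multi_scaffold_required``.  Bemis–Murcko scaffolds (rings plus linkers)
are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import rdRGroupDecomposition
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem import (
    HYDROGEN,
    ContractError,
    Fragment,
    Molecule,
    assemble,
    canonicalize,
    cut_bond,
    heavy_atom_count,
    mol_from_smiles,
    relabel_site,
)
from .series import MMS, AnalogSeries, decompose_mms

STATUS_OK = "ok"
STATUS_AMBIGUOUS = "ambiguous_mapping"
STATUS_MULTI_SCAFFOLD = "multi_scaffold_required"


@dataclass(frozen=True)
class NonredundantCore:
    """A retained exchange core with the merged membership of the cores it subsumes."""

    core: Fragment
    mms_members: frozenset[str]


@dataclass
class SiteMap:
    """Substitution-site bonds marked in one analog.

    Bonds are (scaffold-side atom, substituent-side atom) pairs in the
    analog's canonical structure; a bond marked by several cores counts
    once.
    """

    analog_id: str
    site_bonds: tuple[tuple[int, int], ...]
    ambiguous: bool = False
    conflicting: bool = False  # same bond claimed scaffold-side by both ends


@dataclass
class ASBScaffold:
    """The unique scaffold of an analog series, with numbered sites."""

    structure: str
    n_sites: int
    generation: str  # "first" | "second"
    series_id: str
    member_count: int
    targets: tuple[str, ...] = ()


@dataclass
class ScaffoldResult:
    series_id: str
    status: str
    scaffold: ASBScaffold | None = None


@dataclass
class RGroupTable:
    """Per-member substituents at each scaffold site (regeneration-closed)."""

    scaffold: ASBScaffold
    rows: dict[str, dict[int, str]] = field(default_factory=dict)


def is_core_extension(big: Fragment, small: Fragment) -> bool:
    """True iff ``big`` equals ``small`` with its attachment point replaced
    by a connected piece that carries ``big``'s attachment point.

    Checked constructively: cutting some acyclic bond of ``big`` must leave
    ``small`` as the piece not containing ``big``'s attachment point.
    Strict: a core is not an extension of itself.
    """
    if big.heavy_atoms <= small.heavy_atoms:
        return False
    small_structure = relabel_site(small.structure, 1)
    mol = mol_from_smiles(big.structure)
    dummy_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    for bond in mol.GetBonds():
        if bond.IsInRing():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if dummy_idx in (i, j):
            continue
        piece_i, piece_j = cut_bond(mol, i, j, site=1)
        # the candidate is the piece NOT containing big's own attachment
        # point, i.e. the piece whose only dummy atom is the new cap
        for piece in (piece_i, piece_j):
            if piece.count("*") == 1 and piece == small_structure:
                return True
    return False


def reduce_cores(series: AnalogSeries, mmses: list[MMS] | None = None) -> list[NonredundantCore]:
    """Remove cores that extend a smaller core; merge their memberships.

    Retained cores are pairwise non-extension-related (the minimal elements
    of the extension partial order).  The membership of each removed core is
    merged into every retained core it extends.
    """
    mmses = decompose_mms(series) if mmses is None else mmses
    members_of: dict[str, set[str]] = {}
    frag_of: dict[str, Fragment] = {}
    for mms in mmses:
        members_of.setdefault(mms.core.structure, set()).update(mms.members)
        frag_of[mms.core.structure] = mms.core
    structures = sorted(members_of)
    retained = [
        s
        for s in structures
        if not any(t != s and is_core_extension(frag_of[s], frag_of[t]) for t in structures)
    ]
    merged = {s: set(members_of[s]) for s in retained}
    for s in structures:
        if s in merged:
            continue
        for t in retained:
            if is_core_extension(frag_of[s], frag_of[t]):
                merged[t] |= members_of[s]
    return [NonredundantCore(frag_of[s], frozenset(merged[s])) for s in retained]


def map_sites(
    series: AnalogSeries,
    cores: list[NonredundantCore],
    molecules: dict[str, Molecule],
) -> list[SiteMap]:
    """Transfer the substitution sites of the nonredundant cores onto analogs.

    A core marks the bond of an analog whose cleavage leaves exactly that
    core; bonds marked by several cores are de-duplicated.  A core matching
    one analog at several bonds is accepted only when all matches leave the
    same canonical remainder (symmetry-equivalent); otherwise, or when two
    cores mark the same bond with opposite orientations, the analog is
    flagged ambiguous.
    """
    lookup = {relabel_site(c.core.structure, 1): c.core.structure for c in cores}
    maps: list[SiteMap] = []
    for analog_id in series.members:
        mol = mol_from_smiles(molecules[analog_id].structure, context=analog_id)
        hits: dict[str, list[tuple[int, int, str]]] = {}
        for bond in mol.GetBonds():
            if bond.IsInRing():
                continue
            i, j = sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            piece_i, piece_j = cut_bond(mol, i, j, site=1)
            if piece_i in lookup:
                hits.setdefault(piece_i, []).append((i, j, piece_j))
            if piece_j in lookup:
                hits.setdefault(piece_j, []).append((j, i, piece_i))
        ambiguous = False
        site_bonds: set[tuple[int, int]] = set()
        for core_structure in sorted(hits):
            matches = sorted(hits[core_structure])
            remainders = {canonicalize(rem) for _, _, rem in matches}
            if len(remainders) > 1:
                ambiguous = True
                continue
            site_bonds.add(matches[0][:2])
        conflicting = any((j, i) in site_bonds for i, j in site_bonds)
        maps.append(SiteMap(analog_id, tuple(sorted(site_bonds)), ambiguous, conflicting))
    return maps


def renumber_sites(piece: Chem.Mol) -> tuple[str, dict[int, int]]:
    """Renumber attachment points 1..n by canonical atom rank.

    Returns the canonical SMILES and the mapping from each dummy's previous
    label (0 for unlabeled) to its new site index.  Identical pieces
    obtained from different analogs yield the identical string.
    """
    old_labels = {
        a.GetIdx(): a.GetAtomMapNum() for a in piece.GetAtoms() if a.GetAtomicNum() == 0
    }
    rw = Chem.RWMol(piece)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(0)
            atom.SetIsotope(0)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    dummies = sorted(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0),
        key=lambda idx: ranks[idx],
    )
    mapping: dict[int, int] = {}
    for site, idx in enumerate(dummies, start=1):
        mol.GetAtomWithIdx(idx).SetAtomMapNum(site)
        mapping[old_labels[idx]] = site
    return Chem.MolToSmiles(mol), mapping


def number_sites(piece: Chem.Mol) -> str:
    """Canonical SMILES of a scaffold piece with sites renumbered 1..n."""
    return renumber_sites(piece)[0]


def _extract_remainder(structure: str, site_bonds: tuple[tuple[int, int], ...]) -> str | None:
    """Cut all marked bonds; return the renumbered piece holding every
    scaffold-side atom, or None if those atoms end up in different pieces."""
    mol = mol_from_smiles(structure)
    bond_ids = []
    for i, j in site_bonds:
        bond = mol.GetBondBetweenAtoms(i, j)
        if bond is None or bond.IsInRing():
            return None
        bond_ids.append(bond.GetIdx())
    frag = Chem.FragmentOnBonds(mol, bond_ids, addDummies=True, dummyLabels=[(0, 0)] * len(bond_ids))
    scaffold_side = {i for i, _ in site_bonds}
    for atoms, piece in zip(Chem.GetMolFrags(frag), Chem.GetMolFrags(frag, asMols=True)):
        if scaffold_side <= set(atoms):
            return number_sites(piece)
    return None


def decompose_members(
    scaffold_structure: str, structures: dict[str, str]
) -> dict[str, dict[int, str]] | None:
    """R-group decomposition of members against a multi-site scaffold.

    Returns per-member rows mapping site -> substituent fragment (or the
    hydrogen sentinel), or None if any member fails to match with exactly
    one branch per labeled site.  Rows are verified by reattachment:
    assembling every row must reproduce the member exactly.
    """
    core = mol_from_smiles(scaffold_structure)
    n_sites = sum(1 for a in core.GetAtoms() if a.GetAtomicNum() == 0)
    ids = sorted(structures)
    mols = [mol_from_smiles(structures[i], context=i) for i in ids]
    params = rdRGroupDecomposition.RGroupDecompositionParameters()
    params.onlyMatchAtRGroups = True
    params.removeHydrogensPostMatch = True
    raw_rows, unmatched = rdRGroupDecomposition.RGroupDecompose(
        [core], mols, asSmiles=True, options=params
    )
    if unmatched:
        return None
    rows: dict[str, dict[int, str]] = {}
    for mol_id, raw in zip(ids, raw_rows):
        row: dict[int, str] = {}
        for site in range(1, n_sites + 1):
            value = raw.get(f"R{site}")
            if value is None or heavy_atom_count(value) == 0:
                row[site] = HYDROGEN
            else:
                if value.count("*") != 1:
                    return None  # several branches collapsed into one group
                row[site] = canonicalize(value)
        try:
            regenerated = assemble(scaffold_structure, row)
        except ContractError:
            return None
        if regenerated != structures[mol_id]:
            return None
        rows[mol_id] = row
    return rows


def derive_scaffold(
    series: AnalogSeries,
    molecules: dict[str, Molecule],
    mmses: list[MMS] | None = None,
) -> ScaffoldResult:
    """Derive the unique ASB scaffold of a series, or an exclusion reason."""
    mmses = decompose_mms(series) if mmses is None else mmses
    qualifying: dict[str, set[str]] = {}
    for mms in mmses:
        qualifying.setdefault(mms.core.structure, set()).update(mms.members)
    all_members = set(series.members)
    pre_unique = len(qualifying) == 1 and next(iter(qualifying.values())) == all_members

    retained = reduce_cores(series, mmses)
    if len(retained) == 1 and set(retained[0].mms_members) == all_members:
        structure = relabel_site(retained[0].core.structure, 1)
        scaffold = ASBScaffold(
            structure=structure,
            n_sites=1,
            generation="first" if pre_unique else "second",
            series_id=series.id,
            member_count=len(series.members),
        )
        return ScaffoldResult(series.id, STATUS_OK, scaffold)

    site_maps = map_sites(series, retained, molecules)
    if any(sm.conflicting for sm in site_maps):
        # opposite cores claim the two sides of one bond: no single scaffold
        # can represent both sub-series
        return ScaffoldResult(series.id, STATUS_MULTI_SCAFFOLD)
    if any(sm.ambiguous for sm in site_maps):
        return ScaffoldResult(series.id, STATUS_AMBIGUOUS)
    max_sites = max(len(sm.site_bonds) for sm in site_maps)
    if max_sites == 0:
        return ScaffoldResult(series.id, STATUS_MULTI_SCAFFOLD)
    candidates = sorted(
        (sm for sm in site_maps if len(sm.site_bonds) == max_sites),
        key=lambda sm: molecules[sm.analog_id].structure,
    )
    remainders = {
        _extract_remainder(molecules[sm.analog_id].structure, sm.site_bonds)
        for sm in candidates
    }
    if None in remainders or len(remainders) != 1:
        return ScaffoldResult(series.id, STATUS_AMBIGUOUS)
    candidate = remainders.pop()
    rows = decompose_members(candidate, {m: molecules[m].structure for m in series.members})
    if rows is None:
        return ScaffoldResult(series.id, STATUS_MULTI_SCAFFOLD)
    scaffold = ASBScaffold(
        structure=candidate,
        n_sites=max_sites,
        generation="second",
        series_id=series.id,
        member_count=len(series.members),
    )
    return ScaffoldResult(series.id, STATUS_OK, scaffold)


def build_rgroup_table(
    series: AnalogSeries, scaffold: ASBScaffold, molecules: dict[str, Molecule]
) -> RGroupTable:
    """R-group table of an accepted scaffold (regeneration-closed).

    Raises :class:`ContractError` if any member fails to decompose — an
    accepted scaffold must decompose every member by construction.
    """
    rows = decompose_members(
        scaffold.structure, {m: molecules[m].structure for m in series.members}
    )
    if rows is None:
        raise ContractError(
            f"series {series.id}: accepted scaffold does not decompose all members"
        )
    return RGroupTable(scaffold=scaffold, rows=rows)


def is_anchored_substructure(scaffold_structure: str, structure: str) -> bool:
    """True if the scaffold (attachment points as wildcards) matches the molecule."""
    query = mol_from_smiles(scaffold_structure)
    params = Chem.AdjustQueryParameters.NoAdjustments()
    params.makeDummiesQueries = True
    query = Chem.AdjustQueryProperties(query, params)
    mol = Chem.AddHs(mol_from_smiles(structure))
    return mol.HasSubstructMatch(query)


def bemis_murcko(mol: Molecule) -> str | None:
    """Bemis–Murcko scaffold: rings plus ring-connecting linkers.

    Returns None for acyclic molecules, which have no such scaffold.
    """
    scaffold = MurckoScaffold.GetScaffoldForMol(mol_from_smiles(mol.structure, context=mol.id))
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(scaffold)
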
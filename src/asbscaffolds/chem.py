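"""Molecule model, canonicalization and structure arithmetic.

Everything downstream (fragmentation, matched-pair indexing, scaffold
derivation) works on canonical SMILES strings produced here, so that plain
string equality coincides with chemical identity.  Fragments carry exactly
one attachment point written as a mapped dummy atom ``[*:k]``; ``k`` is the
substitution-site index (always 1 for pre-scaffold fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.warning")
RDLogger.DisableLog("rdApp.error")

#: Sentinel used as the R-group value when a member carries no substituent
#: at a scaffold site (multi-site tables only).
HYDROGEN = "[H]"


class ParseError(ValueError):
    """Raised when a structure cannot be parsed, naming the offending record."""


class ContractError(ValueError):
    """Raised when fragment arithmetic is called with inconsistent inputs."""


def mol_from_smiles(smiles: str, context: str | None = None) -> Chem.Mol:
    """Parse SMILES into an RDKit molecule or raise :class:`ParseError`."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        where = f" ({context})" if context else ""
        raise ParseError(f"unparsable structure{where}: {smiles!r}")
    return mol


def canonicalize(smiles: str, keep_stereo: bool = True, context: str | None = None) -> str:
    """Return the canonical SMILES of a molecule or fragment.

    Idempotent; chemically identical inputs map to identical strings.
    """
    mol = mol_from_smiles(smiles, context)
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms; attachment-point dummies are not counted."""
    mol = mol_from_smiles(smiles)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def standardize(smiles: str, keep_stereo: bool = True, context: str | None = None) -> str:
    """Standardize a compound on ingest.

    Keeps the largest organic component (salt/solvent stripping) and
    neutralizes charges where a neutral form exists, then canonicalizes.
    """
    mol = mol_from_smiles(smiles, context)
    if mol.GetNumAtoms() == 0:
        raise ParseError(f"empty structure ({context})" if context else "empty structure")
    chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
    mol = chooser.choose(mol)
    mol = rdMolStandardize.Uncharger().uncharge(mol)
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _dummy_atoms(mol: Chem.Mol) -> list[Chem.Atom]:
    return [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def attachment_sites(smiles: str) -> list[int]:
    """Site labels of the attachment points in a fragment, sorted."""
    mol = mol_from_smiles(smiles)
    return sorted(a.GetAtomMapNum() for a in _dummy_atoms(mol))


def relabel_site(fragment: str, site: int) -> str:
    """Return the fragment with its single attachment point labeled ``site``."""
    mol = mol_from_smiles(fragment)
    dummies = _dummy_atoms(mol)
    if len(dummies) != 1:
        raise ContractError(f"expected one attachment point: {fragment!r}")
    dummies[0].SetAtomMapNum(site)
    return Chem.MolToSmiles(mol)


def _cap_with_hydrogen(mol: Chem.Mol, sites: Iterable[int]) -> Chem.Mol:
    sites = set(sites)
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() in sites:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.RemoveHs(out)


def cap_all_sites(fragment: str) -> str:
    """Replace every attachment point of a fragment by hydrogen."""
    mol = mol_from_smiles(fragment)
    sites = [a.GetAtomMapNum() for a in _dummy_atoms(mol)]
    return Chem.MolToSmiles(_cap_with_hydrogen(mol, sites))


def attach(core: str, substituent: str) -> str:
    """Bond a one-site core and substituent at their shared attachment point.

    ``substituent`` may be the :data:`HYDROGEN` sentinel, in which case the
    core's attachment point is replaced by hydrogen.  Inverse of a single
    cut: attaching the two fragments produced by cutting molecule M yields M.
    """
    core_mol = mol_from_smiles(core)
    core_sites = [a.GetAtomMapNum() for a in _dummy_atoms(core_mol)]
    if len(core_sites) != 1:
        raise ContractError(f"core must carry exactly one attachment point: {core!r}")
    if substituent == HYDROGEN:
        return Chem.MolToSmiles(_cap_with_hydrogen(core_mol, core_sites))
    sub_mol = mol_from_smiles(substituent)
    sub_sites = [a.GetAtomMapNum() for a in _dummy_atoms(sub_mol)]
    if len(sub_sites) != 1 or sub_sites != core_sites:
        raise ContractError(
            f"attachment labels do not match: core {core!r} vs substituent {substituent!r}"
        )
    joined = Chem.molzip(Chem.CombineMols(core_mol, sub_mol))
    return Chem.MolToSmiles(joined)


def assemble(scaffold: str, rgroups: Mapping[int, str]) -> str:
    """Reattach one substituent (or :data:`HYDROGEN`) per site of a scaffold.

    ``rgroups`` maps every site label of the scaffold to a fragment whose
    attachment point carries the same label.
    """
    scaf = mol_from_smiles(scaffold)
    sites = {a.GetAtomMapNum() for a in _dummy_atoms(scaf)}
    if set(rgroups) != sites:
        raise ContractError(f"rgroup sites {sorted(rgroups)} != scaffold sites {sorted(sites)}")
    h_sites = [k for k, v in rgroups.items() if v == HYDROGEN]
    combined = _cap_with_hydrogen(scaf, h_sites) if h_sites else scaf
    for site in sorted(sites - set(h_sites)):
        frag = mol_from_smiles(rgroups[site])
        frag_sites = [a.GetAtomMapNum() for a in _dummy_atoms(frag)]
        if frag_sites != [site]:
            raise ContractError(f"substituent {rgroups[site]!r} does not carry site {site}")
        combined = Chem.CombineMols(combined, frag)
    joined = Chem.molzip(combined)
    joined = Chem.RemoveHs(joined)
    return Chem.MolToSmiles(joined)


def cut_bond(mol: Chem.Mol, atom_i: int, atom_j: int, site: int = 1) -> tuple[str, str]:
    """Cut the bond between two atoms, capping both new ends with ``[*:site]``.

    Returns canonical SMILES ``(piece containing atom_i, piece containing
    atom_j)``.  The bond must be acyclic.  The bond order is preserved on the
    bonds to the attachment dummies, so :func:`attach` restores the parent.
    """
    bond = mol.GetBondBetweenAtoms(atom_i, atom_j)
    if bond is None or bond.IsInRing():
        raise ContractError(f"no acyclic bond between atoms {atom_i} and {atom_j}")
    frag = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)])
    for atom in frag.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope() == 0 and atom.GetAtomMapNum() == 0:
            atom.SetAtomMapNum(site)
    groups = Chem.GetMolFrags(frag)
    mols = Chem.GetMolFrags(frag, asMols=True)
    piece_i = piece_j = None
    for atoms, piece in zip(groups, mols):
        if atom_i in atoms:
            piece_i = Chem.MolToSmiles(piece)
        if atom_j in atoms:
            piece_j = Chem.MolToSmiles(piece)
    if piece_i is None or piece_j is None or piece_i is piece_j:
        raise ContractError(f"cutting bond {atom_i}-{atom_j} did not split the molecule")
    return piece_i, piece_j


@dataclass
class Molecule:
    """A standardized compound with identifier, canonical structure, targets."""

    id: str
    structure: str
    heavy_atoms: int = 0
    targets: set[str] = field(default_factory=set)
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.heavy_atoms:
            self.heavy_atoms = heavy_atom_count(self.structure)
        if self.heavy_atoms < 1:
            raise ContractError(f"molecule {self.id} has no heavy atoms")

    @classmethod
    def from_smiles(cls, mol_id: str, raw: str, keep_stereo: bool = True) -> "Molecule":
        return cls(id=mol_id, structure=standardize(raw, keep_stereo, context=mol_id))


@dataclass(frozen=True)
class Fragment:
    """A structure with exactly one labeled attachment point."""

    structure: str
    heavy_atoms: int

    @classmethod
    def from_smiles(cls, smiles: str) -> "Fragment":
        canonical = canonicalize(smiles)
        sites = attachment_sites(canonical)
        if len(sites) != 1:
            raise ContractError(f"fragment must have one attachment point: {smiles!r}")
        n_heavy = heavy_atom_count(canonical)
        if n_heavy < 1:
            raise ContractError(f"fragment has no heavy atoms: {smiles!r}")
        return cls(structure=canonical, heavy_atoms=n_heavy)

    @property
    def site(self) -> int:
        return attachment_sites(self.structure)[0]


def merge_duplicates(molecules: Iterable[Molecule]) -> list[Molecule]:
    """Merge compounds with identical canonical structure.

    The lexicographically smallest id is kept; other ids become aliases and
    target annotations are unioned.  Required because a matched pair needs
    two distinct compounds.
    """
    by_structure: dict[str, list[Molecule]] = {}
    for mol in molecules:
        by_structure.setdefault(mol.structure, []).append(mol)
    merged = []
    for structure, group in by_structure.items():
        ids = sorted({m.id for m in group} | {a for m in group for a in m.aliases})
        targets: set[str] = set()
        for m in group:
            targets |= m.targets
        merged.append(
            Molecule(
                id=ids[0],
                structure=structure,
                heavy_atoms=group[0].heavy_atoms,
                targets=targets,
                aliases=tuple(ids[1:]),
            )
        )
    return sorted(merged, key=lambda m: m.id)
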
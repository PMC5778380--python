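"""Single-cut retrosynthetic (RECAP) fragmentation and size restrictions.

A molecule is fragmented at every acyclic bond matching one of the eleven
classical retrosynthetic bond types.  Each cleavable bond yields two
complementary fragments; both orientations (fragment as core vs. as
substituent) are recorded, because matched-pair indexing needs the fragment
pair keyed either way.  Cuts are strictly single-site: one bond per record.

Exchanged substituents are subject to size restrictions so that only
modifications typical of analog series qualify: the core must be at least
``core_to_sub_ratio`` times heavier than either substituent, substituents
may not exceed ``max_sub_heavy`` heavy atoms, and the exchanged pair may not
differ by more than ``max_diff_heavy`` heavy atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .chem import ContractError, Fragment, Molecule, cut_bond, mol_from_smiles

# Retrosynthetic bond catalog.  Each SMARTS tags the two bond atoms with
# atom maps :1 and :2; the bond between them is the cut bond.  All bonds are
# acyclic (!@).  The olefin rule is the one double-bond cleavage of the
# classical catalog; the bond order survives on the attachment dummies so a
# cut always round-trips through reattachment.
RECAP_RULES: tuple[tuple[str, str], ...] = (
    ("amide", "[C;$(C=O);!$(C(=O)[O,S]);!$(C([#7])[#7]):1]!@[#7;+0;!D1;!$([#7]=*):2]"),
    ("ester", "[C;$(C=O);!$(C([#7])):1]!@[#8;D2;+0:2]"),
    ("amine", "[N;+0;!D1;!$(N[C,S]=[O,S,N,P]);!$(N=*);!$(N#*):1]!@[C;!$(C=*);!$(C#*):2]"),
    ("urea", "[#7;+0;D2,D3:1]!@[C;$(C(=O)([#7])[#7]):2]"),
    ("ether", "[#6:1]!@[O;D2;+0;!$(O[C,S]=[O,S,N]):2]"),
    ("olefin", "[C;+0;!$(C=[O,N,S]):1]=!@[C;+0;!$(C=[O,N,S]):2]"),
    ("quaternary_N", "[N;+1;D4:1]!@[#6:2]"),
    ("aromatic_N_aliphatic_C", "[n;+0:1]!@[C;!$(C=[O,S,N]);!$(C#*):2]"),
    ("lactam_N_aliphatic_C", "[N;+0;R;$(N(@[C;R]=O)):1]!@[C;!$(C=[O,S,N]);!$(C#*):2]"),
    ("aromatic_C_aromatic_C", "[c:1]!@[c:2]"),
    ("sulfonamide", "[S;$(S(=O)=O):1]!@[#7;+0;!D1:2]"),
)

RULE_IDS: tuple[str, ...] = tuple(rule_id for rule_id, _ in RECAP_RULES)

_COMPILED: dict[str, tuple[Chem.Mol, int, int]] = {}


def _compiled_rules(subset: tuple[str, ...] | None = None):
    """Compile rule SMARTS once; return (rule_id, pattern, map positions)."""
    wanted = RULE_IDS if subset is None else subset
    out = []
    for rule_id in wanted:
        if rule_id not in _COMPILED:
            smarts = dict(RECAP_RULES)[rule_id]
            patt = Chem.MolFromSmarts(smarts)
            pos = {a.GetAtomMapNum(): a.GetIdx() for a in patt.GetAtoms() if a.GetAtomMapNum()}
            _COMPILED[rule_id] = (patt, pos[1], pos[2])
        out.append((rule_id, *_COMPILED[rule_id]))
    return out


@dataclass(frozen=True)
class SizeRestrictionConfig:
    """Limits on exchanged substituents, in heavy atoms."""

    core_to_sub_ratio: float = 2.0
    max_sub_heavy: int = 13
    max_diff_heavy: int = 8

    def __post_init__(self) -> None:
        if self.core_to_sub_ratio <= 0 or self.max_sub_heavy <= 0 or self.max_diff_heavy <= 0:
            raise ContractError("size restriction values must be strictly positive")


def passes_size_restriction(
    core: Fragment, sub_a: Fragment, sub_b: Fragment, cfg: SizeRestrictionConfig
) -> bool:
    biggest = max(sub_a.heavy_atoms, sub_b.heavy_atoms)
    return (
        core.heavy_atoms >= cfg.core_to_sub_ratio * biggest
        and biggest <= cfg.max_sub_heavy
        and abs(sub_a.heavy_atoms - sub_b.heavy_atoms) <= cfg.max_diff_heavy
    )


@dataclass(frozen=True)
class FragmentationRecord:
    """One single-cut decomposition of a parent molecule.

    ``core_atom``/``sub_atom`` are the cut-bond atom indices in the parent's
    canonical structure (core side / substituent side).
    """

    parent_id: str
    core: Fragment
    substituent: Fragment
    rule_id: str
    core_atom: int
    sub_atom: int


def cleavable_bonds(mol: Chem.Mol, rules: tuple[str, ...] | None = None) -> dict[tuple[int, int], str]:
    """Map each cleavable acyclic bond (i, j) with i < j to its rule id.

    A bond matched by several rules is attributed to the first rule in
    catalog order.  Double bonds with defined stereochemistry are skipped
    (cutting them would lose the configuration and break round-tripping).
    """
    found: dict[tuple[int, int], str] = {}
    for rule_id, patt, p1, p2 in _compiled_rules(rules):
        for match in mol.GetSubstructMatches(patt):
            i, j = match[p1], match[p2]
            bond = mol.GetBondBetweenAtoms(i, j)
            if bond is None or bond.IsInRing():
                continue
            if bond.GetStereo() != Chem.BondStereo.STEREONONE:
                continue
            key = (min(i, j), max(i, j))
            found.setdefault(key, rule_id)
    return found


def enumerate_cuts(
    mol: Molecule, rules: tuple[str, ...] | None = None
) -> list[FragmentationRecord]:
    """All single-cut fragmentations of a molecule under the rule catalog.

    Each cleavable bond yields two records (each fragment once as core).  A
    molecule with no cleavable bond returns the empty list.
    """
    rdmol = mol_from_smiles(mol.structure, context=mol.id)
    records: list[FragmentationRecord] = []
    for (i, j), rule_id in sorted(cleavable_bonds(rdmol, rules).items()):
        piece_i, piece_j = cut_bond(rdmol, i, j, site=1)
        frag_i = Fragment.from_smiles(piece_i)
        frag_j = Fragment.from_smiles(piece_j)
        records.append(
            FragmentationRecord(mol.id, frag_i, frag_j, rule_id, core_atom=i, sub_atom=j)
        )
        records.append(
            FragmentationRecord(mol.id, frag_j, frag_i, rule_id, core_atom=j, sub_atom=i)
        )
    return records
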
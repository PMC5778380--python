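"""Ground-truth benchmark generator for the extraction pipeline.

Builds analog series from hand-written scaffold templates whose 1-3
substitution sites sit on retrosynthetically cleavable linkages (amide,
ester, biaryl, sulfonamide), so that every generated member can be cut back
into scaffold + substituent by the fragmentation rules.  Template interiors
are fused ring systems with no cleavable bonds, and substituents are drawn
from alphabets that (a) contain no cleavable bonds themselves and (b) stay
within the default size restrictions relative to the template.  Each series
gets a unique scaffold by decorating ring positions with small inert groups
(F, Cl, methyl, ethyl); decoy singletons are ring systems with no cleavable
bond at all.

For series with two or more sites, members are realized as a "star" around
a base combination — one site varied at a time — never the full substituent
cross-product, so recovery is tested on observed combinations only.  The
generator records the expected scaffold (in pipeline site numbering), the
per-member R-group rows, and per-series target annotations; it emulates
algorithmic structure, not realistic medicinal-chemistry property
distributions.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

from rdkit import Chem

from .chem import Molecule, assemble, heavy_atom_count, mol_from_smiles, relabel_site
from .recap import SizeRestrictionConfig, enumerate_cuts
from .scaffolds import renumber_sites

# site link types -> substituent alphabets ([*:1]-labeled; relabeled per site)
SUBSTITUENTS: dict[str, tuple[str, ...]] = {
    "amide": (
        "[*:1]C(C)=O",
        "[*:1]C(=O)CC",
        "[*:1]C(=O)CF",
        "[*:1]C(=O)CO",
        "[*:1]C(=O)CCC",
        "[*:1]C(=O)C(C)C",
        "[*:1]C(=O)CCO",
        "[*:1]C(=O)C(F)(F)F",
        "[*:1]C(=O)CCCC",
        "[*:1]C(=O)CC(C)C",
        "[*:1]C(=O)c1ccccc1",
        "[*:1]C(=O)Cc1ccccc1",
    ),
    "ester": (
        "[*:1]OC",
        "[*:1]OCC",
        "[*:1]OCCF",
        "[*:1]OCCC",
        "[*:1]OC(C)C",
        "[*:1]OCCO",
        "[*:1]OCCCC",
        "[*:1]OCC(C)C",
        "[*:1]OC(C)(C)C",
        "[*:1]OCCCCC",
        "[*:1]OCc1ccccc1",
    ),
    "sulfonamide": (
        "[*:1]NC",
        "[*:1]NCC",
        "[*:1]N(C)C",
        "[*:1]NCCC",
        "[*:1]N(C)CC",
        "[*:1]NC(C)C",
        "[*:1]NCCCC",
        "[*:1]N(CC)CC",
        "[*:1]N1CCCC1",
        "[*:1]N1CCCCC1",
        "[*:1]Nc1ccccc1",
    ),
    "biaryl": (
        "[*:1]c1ccccc1",
        "[*:1]c1ccc(C)cc1",
        "[*:1]c1ccc(F)cc1",
        "[*:1]c1cccc(C)c1",
        "[*:1]c1ccc(Cl)cc1",
        "[*:1]c1ccc(C)c(C)c1",
        "[*:1]c1ccc(CC)cc1",
        "[*:1]c1ccc(F)cc1F",
    ),
}


@dataclass(frozen=True)
class Template:
    name: str
    structure: str  # SMILES with [*:1..n]
    links: tuple[str, ...]  # link type per site label 1..n


TEMPLATES: dict[int, tuple[Template, ...]] = {
    1: (
        Template("naphthalen-2-amine", "[*:1]Nc1ccc2ccccc2c1", ("amide",)),
        Template("anthracen-2-amine", "[*:1]Nc1ccc2cc3ccccc3cc2c1", ("amide",)),
        Template("naphthalene-2-carbonyl", "O=C([*:1])c1ccc2ccccc2c1", ("ester",)),
        Template("2-aryl-anthracene", "[*:1]c1ccc2cc3ccccc3cc2c1", ("biaryl",)),
        Template("naphthalene-2-sulfonyl", "O=S(=O)([*:1])c1ccc2ccccc2c1", ("sulfonamide",)),
        Template("quinoline-3-amine", "[*:1]Nc1cnc2ccccc2c1", ("amide",)),
    ),
    2: (
        Template("4-amino-benzoyl", "[*:1]Nc1ccc(C(=O)[*:2])cc1", ("amide", "ester")),
        Template(
            "6-amino-naphthalene-2-carbonyl",
            "[*:1]Nc1ccc2cc(C(=O)[*:2])ccc2c1",
            ("amide", "ester"),
        ),
        Template(
            "4-amino-benzenesulfonyl", "[*:1]Nc1ccc(S(=O)(=O)[*:2])cc1", ("amide", "sulfonamide")
        ),
        Template(
            "6-aryl-anthracene-2-carbonyl",
            "O=C([*:1])c1ccc2cc3cc([*:2])ccc3cc2c1",
            ("ester", "biaryl"),
        ),
    ),
    3: (
        Template(
            "amino-sulfonyl-naphthalene-carbonyl",
            "[*:1]Nc1ccc2cc(C(=O)[*:2])cc(S(=O)(=O)[*:3])c2c1",
            ("amide", "ester", "sulfonamide"),
        ),
        Template(
            "amino-sulfonyl-anthracene-carbonyl",
            "[*:1]Nc1ccc2cc3cc(C(=O)[*:2])cc(S(=O)(=O)[*:3])c3cc2c1",
            ("amide", "ester", "sulfonamide"),
        ),
    ),
}

DECOY_BASES: tuple[str, ...] = (
    "c1ccccc1",
    "C1CCCCC1",
    "c1ccc2ccccc2c1",
    "C1CCCC1",
    "c1ccc2cc3ccccc3cc2c1",
    "C1CCC2CCCCC2C1",
)

_DECORATIONS: tuple[str, ...] = ("F", "Cl", "C", "CC")


class GenerationError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass
class TruthSeries:
    """One generated series with its expected pipeline output."""

    series_index: int
    template: str
    scaffold: str  # pipeline site numbering
    links: dict[int, str]  # site -> link type
    substituents: dict[int, list[str]]  # site -> alphabet used (site-labeled)
    members: dict[str, str]  # member id -> canonical structure
    rows: dict[str, dict[int, str]]  # member id -> site -> substituent
    targets: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    seed: int
    series: list[TruthSeries] = field(default_factory=list)
    decoys: dict[str, str] = field(default_factory=dict)
    activity: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        series = []
        for s in data["series"]:
            s["links"] = {int(k): v for k, v in s["links"].items()}
            s["substituents"] = {int(k): v for k, v in s["substituents"].items()}
            s["rows"] = {m: {int(k): v for k, v in row.items()} for m, row in s["rows"].items()}
            series.append(TruthSeries(**s))
        return cls(
            seed=data["seed"],
            series=series,
            decoys=data["decoys"],
            activity=[tuple(pair) for pair in data["activity"]],
        )


def _decorate(structure: str, rng: random.Random, n_groups: int) -> str:
    """Attach inert groups at ring CH positions; returns SMILES (sites kept)."""
    mol = Chem.RWMol(mol_from_smiles(structure))
    Chem.Kekulize(mol, clearAromaticFlags=True)  # keep H counts valid while editing
    for _ in range(n_groups):
        mol.UpdatePropertyCache(strict=False)
        candidates = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.IsInRing() and a.GetTotalNumHs() >= 1
        ]
        if not candidates:
            break
        pos = rng.choice(sorted(candidates))
        group = rng.choice(_DECORATIONS)
        previous = pos
        for symbol in ([group] if group in ("F", "Cl") else ["C"] * len(group)):
            idx = mol.AddAtom(Chem.Atom(symbol))
            mol.AddBond(previous, idx, Chem.BondType.SINGLE)
            previous = idx
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _scaffold_for_series(
    template: Template, rng: random.Random, used: set[str], cfg: SizeRestrictionConfig
) -> tuple[str, dict[int, int]] | None:
    """Decorated, canonically site-numbered unique scaffold (or None)."""
    for attempt in range(60):
        n_groups = rng.choice((0, 1, 1, 2, 2, 3))
        decorated = _decorate(template.structure, rng, n_groups)
        canonical, mapping = renumber_sites(mol_from_smiles(decorated))
        if canonical not in used:
            return canonical, mapping
    return None


def _allowed_subs(link: str, core_floor: int, cfg: SizeRestrictionConfig) -> list[str]:
    """Substituents guaranteed to pass the size restriction.

    ``core_floor`` is a lower bound on the exchange core: the scaffold plus
    the smallest possible substituent (2 heavy atoms) at every other site.
    """
    limit = min(int(core_floor / cfg.core_to_sub_ratio), cfg.max_sub_heavy)
    return [s for s in SUBSTITUENTS[link] if heavy_atom_count(s) <= limit]


def generate_benchmark(
    sites_distribution: dict[int, int] | None = None,
    subs_per_site: tuple[int, int] = (3, 6),
    n_decoys: int = 30,
    seed: int = 42,
    cfg: SizeRestrictionConfig | None = None,
    n_series: int | None = None,
) -> tuple[list[Molecule], GroundTruth]:
    """Generate a benchmark compound set with ground truth.

    ``sites_distribution`` maps substitution-site count to the number of
    series (default ``{1: 20, 2: 20, 3: 10}``); ``subs_per_site`` is the
    inclusive range of distinct substituents per site.  Deterministic for a
    fixed seed.
    """
    if sites_distribution is None:
        sites_distribution = {1: 20, 2: 20, 3: 10}
    sites_distribution = dict(sites_distribution)
    cfg = cfg or SizeRestrictionConfig()
    total = sum(sites_distribution.values())
    if n_series is not None and n_series != total:
        raise GenerationError(
            f"n_series={n_series} inconsistent with sites distribution (sum {total})"
        )
    if any(n < 0 for n in sites_distribution.values()) or n_decoys < 0:
        raise GenerationError("counts must be non-negative")
    for n_sites, count in sites_distribution.items():
        if count > 0 and n_sites not in TEMPLATES:
            raise GenerationError(f"no scaffold template with {n_sites} substitution sites")
    lo, hi = subs_per_site
    if lo < 2:
        raise GenerationError("each site needs at least two substituents to vary")

    rng = random.Random(seed)
    truth = GroundTruth(seed=seed)
    molecules: list[Molecule] = []
    used_scaffolds: set[str] = set()
    used_structures: set[str] = set()
    target_pool = iter(f"T{i:03d}" for i in range(1, 10_000))

    series_index = 0
    for n_sites in sorted(sites_distribution):
        templates = TEMPLATES.get(n_sites, ())
        for _ in range(sites_distribution[n_sites]):
            template = templates[series_index % len(templates)]
            placed = _scaffold_for_series(template, rng, used_scaffolds, cfg)
            if placed is None:
                raise GenerationError(f"could not derive a unique scaffold from {template.name}")
            scaffold, site_map = placed
            used_scaffolds.add(scaffold)
            scaffold_heavy = heavy_atom_count(scaffold)
            links = {site_map[old + 1]: link for old, link in enumerate(template.links)}
            subs: dict[int, list[str]] = {}
            core_floor = scaffold_heavy + 2 * (len(links) - 1)
            for site in sorted(links):
                allowed = _allowed_subs(links[site], core_floor, cfg)
                k = min(rng.randint(lo, hi), len(allowed))
                if k < 2:
                    raise GenerationError(
                        f"template {template.name}: fewer than two substituents fit the "
                        f"size restriction"
                    )
                chosen = rng.sample(allowed, k)
                subs[site] = [relabel_site(s, site) for s in chosen]

            base = {site: subs[site][0] for site in subs}
            rows: dict[int, dict[int, str]] = {0: dict(base)}
            for site in sorted(subs):
                for alternative in subs[site][1:]:
                    row = dict(base)
                    row[site] = alternative
                    rows[len(rows)] = row
            series_index += 1
            truth_series = TruthSeries(
                series_index=series_index,
                template=template.name,
                scaffold=scaffold,
                links=links,
                substituents=subs,
                members={},
                rows={},
            )
            for member_idx, row in rows.items():
                member_id = f"S{series_index:03d}_{member_idx:02d}"
                structure = assemble(scaffold, row)
                if structure in used_structures:
                    raise GenerationError(f"structure collision for {member_id}: {structure}")
                used_structures.add(structure)
                truth_series.members[member_id] = structure
                truth_series.rows[member_id] = row
                molecules.append(Molecule(id=member_id, structure=structure))
            n_targets = 1 if rng.random() < 0.57 else rng.randint(2, 3)
            truth_series.targets = [next(target_pool) for _ in range(n_targets)]
            members_sorted = sorted(truth_series.members)
            for i, member_id in enumerate(members_sorted):
                target = truth_series.targets[i % n_targets]
                truth.activity.append((member_id, target))
            truth.series.append(truth_series)

    decoy_index = 0
    attempts = 0
    while decoy_index < n_decoys:
        attempts += 1
        if attempts > 50 * max(n_decoys, 1):
            raise GenerationError("could not generate enough unique inert decoys")
        base = rng.choice(DECOY_BASES)
        structure = _decorate(base, rng, rng.choice((0, 1, 2, 3)))
        if structure in used_structures:
            continue
        decoy_id = f"DK{decoy_index + 1:03d}"
        mol = Molecule(id=decoy_id, structure=structure)
        if enumerate_cuts(mol):  # decoys must be inert under the rule catalog
            continue
        used_structures.add(structure)
        truth.decoys[decoy_id] = structure
        truth.activity.append((decoy_id, next(target_pool)))
        molecules.append(mol)
        decoy_index += 1

    truth.activity.sort()
    return molecules, truth


def activity_map(truth: GroundTruth) -> dict[str, set[str]]:
    """Per-compound target sets from the generated activity table."""
    out: dict[str, set[str]] = {}
    for compound_id, target_id in truth.activity:
        out.setdefault(compound_id, set()).add(target_id)
    return out
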
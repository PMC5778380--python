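"""Scaffold derivation: extension reduction, site transfer, exclusions."""

import pytest

from asbscaffolds.chem import Fragment, Molecule, assemble, canonicalize, mol_from_smiles, relabel_site
from asbscaffolds.recap import SizeRestrictionConfig
from asbscaffolds.scaffolds import (
    STATUS_AMBIGUOUS,
    STATUS_MULTI_SCAFFOLD,
    STATUS_OK,
    bemis_murcko,
    build_rgroup_table,
    derive_scaffold,
    is_anchored_substructure,
    is_core_extension,
    map_sites,
    number_sites,
    reduce_cores,
)
from asbscaffolds.series import extract_from_molecules
from asbscaffolds.synthetic import TEMPLATES
from conftest import as_molecules


def canonical_scaffold(smiles: str) -> str:
    """Label-order-independent canonical form for scaffold comparison."""
    return number_sites(mol_from_smiles(smiles))


def molmap(mols):
    return {m.id: m for m in mols}


@pytest.mark.parametrize(
    "big,small,expected",
    [
        ("[*:1]NCC(=O)Nc1ccc2cc3ccccc3cc2c1", "[*:1]Nc1ccc2cc3ccccc3cc2c1", True),
        ("[*:1]Nc1ccc2cc3ccccc3cc2c1", "[*:1]Nc1ccc2cc3ccccc3cc2c1", False),  # strict
        ("[*:1]Nc1ccc2cc3ccccc3cc2c1", "[*:1]NCC(=O)Nc1ccc2cc3ccccc3cc2c1", False),
        ("[*:1]c1ccc2ccccc2c1", "[*:1]C1CCCCC1", False),  # disjoint ring systems
    ],
)
def test_is_core_extension(big, small, expected):
    assert is_core_extension(Fragment.from_smiles(big), Fragment.from_smiles(small)) is expected


def test_extension_series_reduces_two_cores_to_one(extension_pair):
    extraction = extract_from_molecules(extension_pair)
    series = extraction.series[0]
    assert len(series.cores) == 2
    retained = reduce_cores(series)
    assert len(retained) == 1
    assert retained[0].core.structure == canonicalize("[*:1]Nc1ccc2cc3ccccc3cc2c1")
    assert retained[0].mms_members == frozenset({"X1", "X2"})


def test_single_core_series_is_unchanged_by_reduction(three_amides):
    extraction = extract_from_molecules(three_amides)
    retained = reduce_cores(extraction.series[0])
    assert len(retained) == 1
    assert retained[0].core.structure == canonicalize("[*:1]Nc1ccc2ccccc2c1")


def test_two_site_series_retains_both_cores(two_site_abc):
    extraction = extract_from_molecules(two_site_abc)
    retained = reduce_cores(extraction.series[0])
    assert len(retained) == 2


def test_site_transfer_marks_shared_analog_twice(two_site_abc):
    extraction = extract_from_molecules(two_site_abc)
    series = extraction.series[0]
    retained = reduce_cores(series)
    site_maps = {sm.analog_id: sm for sm in map_sites(series, retained, molmap(two_site_abc))}
    assert len(site_maps["A"].site_bonds) == 2
    assert len(site_maps["B"].site_bonds) == 1
    assert len(site_maps["C"].site_bonds) == 1
    assert not any(sm.ambiguous or sm.conflicting for sm in site_maps.values())


def test_first_generation_scaffold_of_three_amides(three_amides):
    extraction = extract_from_molecules(three_amides)
    result = derive_scaffold(extraction.series[0], molmap(three_amides))
    assert result.status == STATUS_OK
    assert result.scaffold.structure == canonicalize("[*:1]Nc1ccc2ccccc2c1")
    assert result.scaffold.n_sites == 1
    assert result.scaffold.generation == "first"
    table = build_rgroup_table(extraction.series[0], result.scaffold, molmap(three_amides))
    assert table.rows == {
        "M1": {1: canonicalize("[*:1]C(=O)C")},
        "M2": {1: canonicalize("[*:1]C(=O)CC")},
        "M3": {1: canonicalize("[*:1]C(=O)CCC")},
    }


def test_two_site_scaffold_and_regeneration(two_site_abc):
    extraction = extract_from_molecules(two_site_abc)
    result = derive_scaffold(extraction.series[0], molmap(two_site_abc))
    assert result.status == STATUS_OK
    assert result.scaffold.n_sites == 2
    assert result.scaffold.generation == "second"
    assert result.scaffold.structure == canonical_scaffold("[*:1]Nc1ccc(C([*:2])=O)cc1")
    table = build_rgroup_table(extraction.series[0], result.scaffold, molmap(two_site_abc))
    for mol in two_site_abc:
        assert assemble(result.scaffold.structure, table.rows[mol.id]) == mol.structure


def test_extension_series_yields_second_generation_single_site(extension_pair):
    extraction = extract_from_molecules(extension_pair)
    result = derive_scaffold(extraction.series[0], molmap(extension_pair))
    assert result.status == STATUS_OK
    assert result.scaffold.n_sites == 1
    assert result.scaffold.generation == "second"
    assert result.scaffold.structure == canonicalize("[*:1]Nc1ccc2cc3ccccc3cc2c1")


def _assemble_series(scaffold, rows):
    return [Molecule(id=k, structure=assemble(scaffold, r)) for k, r in rows.items()]


def test_chained_overlaps_without_hub_analog_are_ambiguous():
    """Three single-site sub-series overlapping pairwise, with no analog
    carrying all sites: the sites cannot be mapped onto one scaffold."""
    scaffold = canonical_scaffold(TEMPLATES[3][0].structure)
    a1, a2 = relabel_site("[*:1]C(C)=O", 1), relabel_site("[*:1]C(=O)CC", 1)
    b0, b1 = relabel_site("[*:1]OC", 2), relabel_site("[*:1]OCC", 2)
    c0, c1 = relabel_site("[*:1]NC", 3), relabel_site("[*:1]NCC", 3)
    rows = {
        "M1": {1: a1, 2: b0, 3: c0},
        "M2": {1: a2, 2: b0, 3: c0},
        "M3": {1: a2, 2: b1, 3: c0},
        "M4": {1: a2, 2: b1, 3: c1},
    }
    mols = _assemble_series(scaffold, rows)
    extraction = extract_from_molecules(mols)
    assert len(extraction.series) == 1
    result = derive_scaffold(extraction.series[0], molmap(mols))
    assert result.status == STATUS_AMBIGUOUS
    assert result.scaffold is None


def test_hub_analog_resolves_the_chain_into_three_sites():
    """Adding an analog that participates in a sub-series at every site
    turns the same chain into a clean three-site scaffold."""
    scaffold = canonical_scaffold(TEMPLATES[3][0].structure)
    a1, a2 = relabel_site("[*:1]C(C)=O", 1), relabel_site("[*:1]C(=O)CC", 1)
    b0, b1 = relabel_site("[*:1]OC", 2), relabel_site("[*:1]OCC", 2)
    c0, c1 = relabel_site("[*:1]NC", 3), relabel_site("[*:1]NCC", 3)
    rows = {
        "M1": {1: a1, 2: b0, 3: c0},
        "M2": {1: a2, 2: b0, 3: c0},
        "M3": {1: a2, 2: b1, 3: c0},
        "M4": {1: a2, 2: b1, 3: c1},
        "M5": {1: a2, 2: b0, 3: c1},  # hub partner: M2 now varies at site 3
    }
    mols = _assemble_series(scaffold, rows)
    extraction = extract_from_molecules(mols)
    result = derive_scaffold(extraction.series[0], molmap(mols))
    assert result.status == STATUS_OK
    assert result.scaffold.n_sites == 3
    assert result.scaffold.structure == scaffold


def test_bridged_frameworks_require_multiple_scaffolds():
    """A compound linking two sub-series whose cores sit on opposite sides
    of the same bond cannot be represented by one scaffold."""
    mols = as_molecules(
        {
            "PAc": "CC(=O)Nc1ccc2ccccc2c1",
            "PPr": "CCC(=O)Nc1ccc2ccccc2c1",
            "Z": "COc1ccccc1C(=O)Nc1ccc2ccccc2c1",
            "W": "COc1ccccc1C(=O)Nc1ccc2cc3ccccc3cc2c1",
        }
    )
    cfg = SizeRestrictionConfig(core_to_sub_ratio=0.5, max_sub_heavy=20, max_diff_heavy=8)
    extraction = extract_from_molecules(mols, cfg)
    assert len(extraction.series) == 1
    result = derive_scaffold(extraction.series[0], molmap(mols))
    assert result.status == STATUS_MULTI_SCAFFOLD
    assert result.scaffold is None


@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("CC(=O)Nc1ccccc1", "c1ccccc1"),
        ("c1ccccc1", "c1ccccc1"),
        ("CCCC", None),
    ],
)
def test_bemis_murcko_scaffolds(smiles, expected):
    result = bemis_murcko(Molecule.from_smiles("m", smiles))
    assert result == (canonicalize(expected) if expected else None)


def test_one_series_one_scaffold_despite_multiple_murcko_frameworks():
    """Members of one analog series with different ring frameworks yield
    several Bemis-Murcko scaffolds but exactly one series scaffold."""
    mols = as_molecules(
        {
            "E1": "CC(=O)Nc1ccc2cc3ccccc3cc2c1",
            "E2": "CCC(=O)Nc1ccc2cc3ccccc3cc2c1",
            "E3": "O=C(Nc1ccc2cc3ccccc3cc2c1)c1ccccc1",
        }
    )
    extraction = extract_from_molecules(mols)
    assert len(extraction.series) == 1
    murcko = {bemis_murcko(m) for m in mols}
    assert len(murcko) >= 2
    result = derive_scaffold(extraction.series[0], molmap(mols))
    assert result.status == STATUS_OK
    assert result.scaffold.structure == canonicalize("[*:1]Nc1ccc2cc3ccccc3cc2c1")


def test_scaffold_is_anchored_substructure_of_every_member(small_benchmark_run):
    result, _ = small_benchmark_run
    molecules = molmap(result.molecules)
    by_id = {s.id: s for s in result.extraction.series}
    for res in result.results:
        if res.status != STATUS_OK:
            continue
        for member in by_id[res.series_id].members:
            assert is_anchored_substructure(res.scaffold.structure, molecules[member].structure)


def test_rgroup_tables_regenerate_members_exactly(small_benchmark_run):
    result, _ = small_benchmark_run
    by_id = {s.id: s for s in result.extraction.series}
    for table in result.tables:
        series = by_id[table.scaffold.series_id]
        regenerated = {
            assemble(table.scaffold.structure, row) for row in table.rows.values()
        }
        member_structures = {
            m.structure for m in result.molecules if m.id in set(series.members)
        }
        assert regenerated == member_structures


def test_removed_cores_are_extensions_of_retained_cores(small_benchmark_run):
    """Reduction soundness: every core dropped by the reduction is reachable
    from a retained core by extension steps."""
    from asbscaffolds.series import decompose_mms

    result, _ = small_benchmark_run
    for series in result.extraction.series:
        mmses = decompose_mms(series)
        qualifying = {m.core.structure: m.core for m in mmses}
        retained = {c.core.structure: c.core for c in reduce_cores(series, mmses)}
        for structure, core in qualifying.items():
            if structure in retained:
                continue
            assert any(is_core_extension(core, kept) for kept in retained.values())
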
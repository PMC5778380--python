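"""Core indexing, RMMP enumeration, and analog series extraction."""

import pytest

from asbscaffolds.chem import Molecule, canonicalize
from asbscaffolds.recap import SizeRestrictionConfig, enumerate_cuts
from asbscaffolds.series import (
    decompose_mms,
    enumerate_rmmps,
    extract_from_molecules,
    extract_series,
    index_cores,
)
from conftest import as_molecules
from helpers import brute_force_rmmp_keys, union_find_components

NAPHTHYLAMINE_CORE = canonicalize("[*:1]Nc1ccc2ccccc2c1")


def records_for(molecules):
    return [rec for mol in molecules for rec in enumerate_cuts(mol)]


def test_index_groups_three_amides_under_shared_core(three_amides):
    index = index_cores(records_for(three_amides))
    assert NAPHTHYLAMINE_CORE in index
    assert sorted(index[NAPHTHYLAMINE_CORE]) == ["M1", "M2", "M3"]


def test_index_of_empty_and_single_molecule_inputs(three_amides):
    assert index_cores([]) == {}
    index = index_cores(records_for(three_amides[:1]))
    assert all(len(parents) == 1 for parents in index.values())


def test_three_amides_give_three_rmmps_on_one_core(three_amides):
    rmmps = enumerate_rmmps(index_cores(records_for(three_amides)), SizeRestrictionConfig())
    assert len(rmmps) == 3
    assert {r.core.structure for r in rmmps} == {NAPHTHYLAMINE_CORE}
    assert {(r.compound_a, r.compound_b) for r in rmmps} == {
        ("M1", "M2"),
        ("M1", "M3"),
        ("M2", "M3"),
    }


def test_identical_structures_give_no_rmmp():
    mols = [Molecule.from_smiles(i, "CC(=O)Nc1ccc2ccccc2c1") for i in ("a", "b")]
    from asbscaffolds.chem import merge_duplicates

    merged = merge_duplicates(mols)
    rmmps = enumerate_rmmps(index_cores(records_for(merged)), SizeRestrictionConfig())
    assert rmmps == []


def test_unrelated_compounds_share_no_core():
    mols = as_molecules({"bz": "c1ccccc1", "ac": "CC(=O)Nc1ccccc1"})
    rmmps = enumerate_rmmps(index_cores(records_for(mols)), SizeRestrictionConfig())
    assert rmmps == []


def test_series_from_amides_plus_decoy(three_amides):
    mols = [*three_amides, Molecule.from_smiles("bz", "c1ccccc1")]
    extraction = extract_from_molecules(mols)
    assert len(extraction.series) == 1
    assert extraction.series[0].members == ("M1", "M2", "M3")
    assert extraction.singletons == ["bz"]


def test_empty_rmmp_list_gives_no_series():
    assert extract_series([]) == []


def test_unrelated_triplets_form_disjoint_series(three_amides):
    others = as_molecules(
        {
            "N1": "CC(=O)Nc1ccc2cc3ccccc3cc2c1",
            "N2": "CCC(=O)Nc1ccc2cc3ccccc3cc2c1",
            "N3": "CCCC(=O)Nc1ccc2cc3ccccc3cc2c1",
        }
    )
    extraction = extract_from_molecules([*three_amides, *others])
    assert len(extraction.series) == 2
    members = [set(s.members) for s in extraction.series]
    assert {"M1", "M2", "M3"} in members and {"N1", "N2", "N3"} in members


def test_series_match_union_find_components(benchmark_50_run):
    """Connected components agree with an independent union-find oracle."""
    result, _truth = benchmark_50_run
    pairs = [(r.compound_a, r.compound_b) for r in result.extraction.rmmps]
    expected = union_find_components(pairs)
    found = {frozenset(s.members) for s in result.extraction.series}
    assert found == expected


def test_rmmp_enumeration_equals_brute_force_all_pairs(three_amides, two_site_abc, small_benchmark):
    """Index-based enumeration equals trying every cut of every compound
    pair and testing fragment equality."""
    molecules, _ = small_benchmark
    subset = [*three_amides, *two_site_abc, *molecules[:12]]
    cfg = SizeRestrictionConfig()
    rmmps = enumerate_rmmps(index_cores(records_for(subset)), cfg)
    found = {(r.compound_a, r.compound_b, r.core.structure) for r in rmmps}
    assert found == brute_force_rmmp_keys(subset, cfg)


def test_three_amide_series_is_one_mms(three_amides):
    extraction = extract_from_molecules(three_amides)
    mmses = decompose_mms(extraction.series[0])
    assert len(mmses) == 1
    assert mmses[0].core.structure == NAPHTHYLAMINE_CORE
    assert sorted(mmses[0].members) == ["M1", "M2", "M3"]


def test_two_member_series_is_the_smallest_mms(three_amides):
    extraction = extract_from_molecules(three_amides[:2])
    mmses = decompose_mms(extraction.series[0])
    assert len(mmses) == 1 and len(mmses[0].members) == 2


def test_two_site_series_decomposes_into_two_mms(two_site_abc):
    extraction = extract_from_molecules(two_site_abc)
    mmses = decompose_mms(extraction.series[0])
    by_core = {m.core.structure: sorted(m.members) for m in mmses}
    assert by_core == {
        canonicalize("CC(=O)Nc1ccc(C(=O)[*:1])cc1"): ["A", "C"],
        canonicalize("[*:1]Nc1ccc(C(=O)OC)cc1"): ["A", "B"],
    }


def test_every_edge_is_covered_by_an_mms(small_benchmark_run):
    result, _ = small_benchmark_run
    for series in result.extraction.series:
        mmses = decompose_mms(series)
        for edge in series.edges:
            assert any(
                edge.compound_a in m.members
                and edge.compound_b in m.members
                and m.core.structure == edge.core.structure
                for m in mmses
            )


def test_compounds_belong_to_at_most_one_series(small_benchmark_run):
    result, _ = small_benchmark_run
    seen: set[str] = set()
    for series in result.extraction.series:
        assert not (set(series.members) & seen)
        seen |= set(series.members)
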
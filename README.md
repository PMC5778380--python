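# asbscaffolds

Analog series extraction and **analog series-based (ASB) scaffolds** for
bioactive compound sets.

Medicinal chemistry organizes compounds into *analog series* (AS): sets of
related molecules sharing a core structure and differing by substituents at
one or more sites. The classical Bemis–Murcko scaffold (all rings plus
ring-connecting linkers of a single compound) is compound-based, so one
series can yield several different scaffolds. ASB scaffolds instead
represent the *series*: each analog series yields one and only one scaffold,
carrying numbered substitution sites, derived only through retrosynthetically
cleavable bonds, and inheriting the target annotations of its series. The
result is an R-group-table-ready core that captures the structure–activity
relationship (SAR) information of the whole series.

## Method

1. **RMMP generation.** Every compound is fragmented at each acyclic bond
   matching one of the eleven classical RECAP retrosynthetic bond types
   (amide, ester, amine, urea, ether, olefin, quaternary N, aromatic
   N–aliphatic C, lactam N–aliphatic C, aromatic C–aromatic C,
   sulfonamide), one cut at a time. Two compounds that share a core and
   differ by one exchanged substituent pair form a RECAP matched molecular
   pair (RMMP). Size restrictions keep the exchanges analog-like: core ≥ 2 ×
   substituent heavy atoms, substituent ≤ 13 heavy atoms, exchange
   difference ≤ 8 heavy atoms (all configurable).
2. **Series extraction.** RMMPs are edges of a network over compounds; each
   connected component is an analog series. Compounds sharing one core form
   a matching molecular series (MMS), a maximal single-site sub-series.
3. **Scaffold derivation.** If a single core covers the whole series, it is
   the (first-generation) ASB scaffold with one site, `[*:1]`. Otherwise
   cores that are structural extensions of a smaller core at the same site
   are removed as redundant, the substitution sites of the remaining
   nonredundant cores are transferred onto the analogs they match, and the
   common remainder after cutting all marked site bonds becomes a
   second-generation scaffold `[*:1]…[*:n]`. Series whose sites cannot be
   mapped onto one scaffold are excluded with an explicit reason
   (`ambiguous_mapping` or `multi_scaffold_required`).
4. **Annotation and statistics.** Series inherit the union of their members'
   target annotations (single- vs multi-target), scaffolds inherit the
   series target set, and a report summarizes counts, coverage percentages
   and per-category statistics.

## Worked example

```python
from asbscaffolds import Molecule, extract_from_molecules, derive_scaffold, build_rgroup_table

mols = [
    Molecule.from_smiles("CHEMBL-A", "CC(=O)Nc1ccc(C(=O)OC)cc1"),
    Molecule.from_smiles("CHEMBL-B", "CCC(=O)Nc1ccc(C(=O)OC)cc1"),
    Molecule.from_smiles("CHEMBL-C", "CC(=O)Nc1ccc(C(=O)OCC)cc1"),
    Molecule.from_smiles("CHEMBL-D", "c1ccccc1"),
]
extraction = extract_from_molecules(mols)
series = extraction.series[0]
molmap = {m.id: m for m in mols}
result = derive_scaffold(series, molmap)
table = build_rgroup_table(series, result.scaffold, molmap)
```

prints (via the obvious `print` calls):

```
series members: ('CHEMBL-A', 'CHEMBL-B', 'CHEMBL-C') | singletons: ['CHEMBL-D']
scaffold: O=C(c1ccc(N[*:1])cc1)[*:2] | sites: 2 | generation: second
CHEMBL-A {1: 'CC(=O)[*:1]', 2: 'CO[*:2]'}
CHEMBL-B {1: 'CCC(=O)[*:1]', 2: 'CO[*:2]'}
CHEMBL-C {1: 'CC(=O)[*:1]', 2: 'CCO[*:2]'}
```

The three esters/amides form one series; benzene has no retrosynthetic cut
and stays a singleton. The amide MMS (A, B) and the ester MMS (A, C) overlap
in compound A, so the series has two substitution sites: R1 varies the acyl
group, R2 the alkoxy group, and reattaching each row regenerates the member
exactly.

The same pipeline is available from the shell:

```bash
asb simulate --sites 1:3,2:2,3:1 --subs 3-4 --decoys 5 --seed 11 \
    --out s.smi --truth t.json --activity a.csv
asb run --in s.smi --activity a.csv --out-dir o
```

```
Compounds (input / in series / singletons): 34 / 29 / 5
Analog series: 6  (size 3-8, mean 4.8)
Targets: 11  (single-target series 2, multi-target 4)
ASB scaffolds: 6  (first generation 3, second 3)
Coverage: 100.0% of series, 100.0% of compounds in series
Single site (first/second): 3 series (50.0%), 9 compounds (31.0%), mean size 3.0, mean sites 1.0, targets 4
Single site (second only): 0 series (0.0%), 0 compounds (0.0%), mean size 0.0, mean sites 0.0, targets 0
Multiple sites (second): 3 series (50.0%), 20 compounds (69.0%), mean size 6.7, mean sites 2.3, targets 7
```

`asb run` writes `frags.tsv`, `edges.tsv`, `series.json`, `scaffolds.tsv`,
per-series R-group tables under `rgroups/`, and `report.json`; the stage
commands (`fragment`, `series`, `scaffolds`, `stats`) produce and consume
the same files individually. Inputs are a SMILES file (one
`structure identifier` pair per line) and an optional activity CSV with
header `compound_id,target_id`.

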
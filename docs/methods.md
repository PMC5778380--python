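# Methods

## Model and assumptions

The package treats an analog series as an emergent object: compounds are
nodes, and an edge exists wherever two compounds can be interconverted by a
single retrosynthetic substituent exchange (an RMMP). Three assumptions
follow from that definition and shape everything downstream:

* **Single-site exchanges only.** Each matched pair differs at exactly one
  bond; multi-site variation within a series is recovered later from
  overlapping single-site sub-series (MMSs), never from multi-cut
  fragmentation.
* **Retrosynthetic bonds only.** Cuts are restricted to a fixed catalog of
  eleven bond types (amide, ester, amine, urea, ether, olefin, quaternary
  nitrogen, aromatic N–aliphatic C, lactam N–aliphatic C, aromatic
  C–aromatic C, sulfonamide), expressed as SMARTS over the two bond atoms
  and applied to acyclic bonds. A bond matched by several rules is
  attributed to the first rule in catalog order. The olefin rule is the one
  double-bond cleavage in the catalog; the bond order is preserved on the
  attachment dummies so every cut reattaches exactly. Double bonds with
  defined E/Z configuration are not cut, because the configuration could
  not be restored on reattachment.
* **Analog-like exchanges only.** An exchange qualifies when the shared
  core has at least `core_to_sub_ratio` (default 2.0) times the heavy atoms
  of either substituent, neither substituent exceeds `max_sub_heavy`
  (default 13) heavy atoms, and the two substituents differ by at most
  `max_diff_heavy` (default 8) heavy atoms. The defaults follow the
  transformation-size conventions commonly used for matched-pair analysis
  and are deliberate assumptions, exposed in the configuration and echoed
  into every artifact header.

Compounds are standardized on ingest: largest organic component kept,
charges neutralized where a neutral form exists, stereochemistry kept by
default (`keep_stereo`, configurable, since curation conventions vary).
Duplicates by canonical structure are merged — ids and target annotations
unioned — because a matched pair requires two distinct compounds.

## Scaffold derivation

Within a series, every core shared by two or more members defines an MMS.
Because the size restrictions compare the two exchanged substituents,
pairwise qualification is not automatically transitive; MMS membership is
therefore taken as maximal cliques of the per-core pair graph (in practice
almost always a single clique).

Derivation then proceeds:

1. **Reduction.** A core that equals a smaller core with its attachment
   point replaced by a connected fragment (carrying the bigger core's
   attachment point) is a *core extension* and redundant. The check is
   constructive: some acyclic bond cut of the big core must leave the small
   core as the piece away from the big core's attachment point. Extension
   is transitive along such chains, so retaining the minimal elements and
   merging the memberships of removed cores into every retained core they
   extend is sound.
2. **Site transfer.** A retained core marks the bond of an analog whose
   cleavage leaves exactly that core. Site identity is the cut bond (atom
   pair) in the analog, not the core that discovered it, so several cores
   marking the same bond collapse to one site. If a core matches one analog
   at several bonds, the match is accepted only when all remainders are
   canonically identical (pure symmetry) — otherwise the series is excluded
   as `ambiguous_mapping`. If two cores claim opposite sides of the same
   bond, no single framework can represent both sub-series and the series
   is excluded as `multi_scaffold_required`.
3. **Extraction.** If exactly one retained core covers all members it is
   the scaffold (one site; generation "first" when it was already the
   unique qualifying core before reduction, "second" otherwise — the
   pre-reduction uniqueness test defines the generation label). Otherwise
   the candidate scaffold is the remainder of a maximally-marked analog
   after cutting all its marked bonds; analogs tying for the maximal site
   count are processed in canonical-structure order and must all yield the
   identical candidate, or the series is excluded as ambiguous.
4. **Validation.** Every member must decompose as candidate plus exactly
   one substituent — or hydrogen — per site (R-group decomposition with
   matching allowed only at labeled sites), and reattaching every row must
   regenerate the member string-exactly. Any failure excludes the series as
   `multi_scaffold_required`. Hydrogen is a legal R-group value only in
   multi-site tables; single-site cores always carry a real substituent
   because cuts never produce empty fragments.

Site numbers follow the canonical atom ranking of the attachment dummies,
so repeated runs and different discovery orders produce byte-identical
scaffold strings. All collection outputs are sorted by canonical keys.

## Synthetic benchmark

The generator emulates the situation the method is designed for: series
built from a scaffold whose 1–3 substitution sites sit on cleavable
linkages (amide, ester, biaryl, sulfonamide), plus inert decoy singletons.
Twelve hand-written templates (9–20 heavy atoms, fused ring interiors with
no cleavable bond) are decorated with inert ring substituents (F, Cl,
methyl, ethyl) to give every series a unique scaffold; substituent
alphabets (2–8 heavy atoms) are filtered per series so all star-pattern
exchanges pass the size restrictions. Multi-site series realize a star
around a base combination (one site varied at a time), never the full
cross-product, so regeneration is only ever asserted for observed
combinations. Per-series target annotations are drawn with a 57%
single-target probability, the proportion reported for curated bioactivity
collections.

What the benchmark does *not* emulate: realistic property distributions,
ring-system diversity, stereochemistry, tautomerism, or the near-miss
exchanges (slightly-too-large substituents, almost-shared cores) that make
real collections messy. Passing it shows the machinery is exact on
constructible ground truth — recovery of partition and scaffolds, exact
regeneration — not that any particular coverage percentage will transfer
to a real compound database. The default benchmark (50 series: 20/20/10
one-/two-/three-site, 3–6 substituents per site, 30 decoys, ~380
molecules) was sized to exercise all code paths while keeping the full
test suite and the acceptance script each under a minute of single-CPU
time.

## Numerical and design choices

* Canonical SMILES equality (RDKit) is the only structure-identity notion;
  fragments carry exactly one `[*:k]` dummy and reattachment uses
  atom-map-guided zipping, making cut/attach exact inverses.
* Heavy-atom counts exclude attachment dummies and hydrogens.
* The RMMP network stores one edge per compound pair per shared core; the
  component structure is identical to a one-edge-per-pair network, and the
  cores are listed separately on each series.
* Percentages are rounded half-up to one decimal. Compound-coverage
  percentages use compounds participating in series as the denominator,
  not all input compounds — both readings are plausible; this one matches
  how series statistics are conventionally tabulated. Singleton counts are
  reported so the other denominator can be recomputed.
* Degenerate inputs: an empty compound set yields empty artifacts and an
  all-zero report with exit status 0; unparsable records abort with the
  file, line number and identifier; activity rows for unknown compound ids
  are logged and skipped.
* A series with a single compound cannot exist (components need an edge),
  and a compound participating in no RMMP is reported in the `singletons`
  audit list.

## Known limitations

* The exclusion taxonomy operationalizes "sites cannot be unambiguously
  mapped" as disagreement between maximally-marked candidates (or
  symmetric matches with differing remainders), and "more than one scaffold
  required" as orientation conflicts or decomposition failure. These are
  validated by the regeneration-closure invariant rather than by fidelity
  to any particular legacy implementation.
* The rule catalog is a fixed, documented interpretation of the classical
  retrosynthetic bond types; other RECAP variants (e.g. cutting N–aryl
  amine bonds, carbamates) would change series composition. The catalog is
  subsettable via configuration.
* Stereochemistry is carried through canonicalization but sites on
  stereo-defined double bonds are never created.
* Scaling is adequate for tens of thousands of compounds but the site
  transfer step re-cuts every acyclic bond of every series member once per
  retained core; very large series are the slowest case.
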
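"""Independent oracles used by the tests.

These deliberately avoid the package's indexing/clustering code paths: the
pair oracle compares every compound pair by trying every single cut of
both molecules, and the clustering oracle is a plain union-find.
"""

from __future__ import annotations

from asbscaffolds.chem import Molecule
from asbscaffolds.recap import SizeRestrictionConfig, enumerate_cuts, passes_size_restriction


def brute_force_rmmp_keys(
    molecules: list[Molecule], cfg: SizeRestrictionConfig
) -> set[tuple[str, str, str]]:
    """(id_a, id_b, core) triples by all-pairs single-cut comparison."""
    cuts = {m.id: enumerate_cuts(m) for m in molecules}
    keys: set[tuple[str, str, str]] = set()
    ids = sorted(cuts)
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            for rec_a in cuts[id_a]:
                for rec_b in cuts[id_b]:
                    if rec_a.core.structure != rec_b.core.structure:
                        continue
                    if rec_a.substituent.structure == rec_b.substituent.structure:
                        continue
                    if passes_size_restriction(
                        rec_a.core, rec_a.substituent, rec_b.substituent, cfg
                    ):
                        keys.add((id_a, id_b, rec_a.core.structure))
    return keys


class UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_components(pairs: list[tuple[str, str]]) -> set[frozenset[str]]:
    uf = UnionFind()
    for a, b in pairs:
        uf.union(a, b)
    groups: dict[str, set[str]] = {}
    for node in uf.parent:
        groups.setdefault(uf.find(node), set()).add(node)
    return {frozenset(g) for g in groups.values()}
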
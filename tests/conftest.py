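"""Shared fixtures: micro compound sets and seeded synthetic benchmarks."""

from __future__ import annotations

import pytest

from asbscaffolds.chem import Molecule
from asbscaffolds.pipeline import run as run_in_memory
from asbscaffolds.synthetic import activity_map, generate_benchmark

THREE_AMIDES = {
    "M1": "CC(=O)Nc1ccc2ccccc2c1",
    "M2": "CCC(=O)Nc1ccc2ccccc2c1",
    "M3": "CCCC(=O)Nc1ccc2ccccc2c1",
}

TWO_SITE_ABC = {
    "A": "CC(=O)Nc1ccc(C(=O)OC)cc1",
    "B": "CCC(=O)Nc1ccc(C(=O)OC)cc1",
    "C": "CC(=O)Nc1ccc(C(=O)OCC)cc1",
}

EXTENSION_PAIR = {
    "X1": "O=CNCC(=O)Nc1ccc2cc3ccccc3cc2c1",
    "X2": "CC(=O)NCC(=O)Nc1ccc2cc3ccccc3cc2c1",
}


def as_molecules(structures: dict[str, str]) -> list[Molecule]:
    return [Molecule.from_smiles(mol_id, smi) for mol_id, smi in structures.items()]


@pytest.fixture(scope="session")
def three_amides() -> list[Molecule]:
    return as_molecules(THREE_AMIDES)


@pytest.fixture(scope="session")
def two_site_abc() -> list[Molecule]:
    return as_molecules(TWO_SITE_ABC)


@pytest.fixture(scope="session")
def extension_pair() -> list[Molecule]:
    return as_molecules(EXTENSION_PAIR)


@pytest.fixture(scope="session")
def small_benchmark():
    """Compact seeded benchmark: 2+2+1 series, 5 decoys."""
    molecules, truth = generate_benchmark(
        {1: 2, 2: 2, 3: 1}, subs_per_site=(3, 4), n_decoys=5, seed=7
    )
    return molecules, truth


@pytest.fixture(scope="session")
def small_benchmark_run(small_benchmark):
    molecules, truth = small_benchmark
    return run_in_memory(molecules, activity_map(truth)), truth


@pytest.fixture(scope="session")
def benchmark_50():
    """Study-condition benchmark: 50 series (20/20/10 sites), 3-6
    substituents per site, 30 decoy singletons, seed 42."""
    molecules, truth = generate_benchmark(
        {1: 20, 2: 20, 3: 10}, subs_per_site=(3, 6), n_decoys=30, seed=42
    )
    return molecules, truth


@pytest.fixture(scope="session")
def benchmark_50_run(benchmark_50):
    molecules, truth = benchmark_50
    return run_in_memory(molecules, activity_map(truth)), truth
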
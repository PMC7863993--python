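"""Shared fixtures: hand-built graphs and small synthetic benchmarks."""

import itertools

import numpy as np
import pytest

from ffbench.io_dataset import Conformer, MolecularGraph
from ffbench.synthetic_data import SynthConfig, generate_benchmark


def make_graph(elements, bonds, title="", charges=None, stereo=None):
    charges = charges or [0] * len(elements)
    stereo = stereo or [None] * len(elements)
    atoms = tuple(zip(elements, charges, stereo))
    return MolecularGraph(atoms=atoms, bonds=tuple(bonds), title=title)


@pytest.fixture
def water_graph():
    return make_graph(["O", "H", "H"], [(0, 1, 1), (0, 2, 1)], title="water")


@pytest.fixture
def chain_cno_graph():
    """Asymmetric heavy chain C-N-O: exactly one automorphism."""
    return make_graph(["C", "N", "O"], [(0, 1, 1), (1, 2, 1)])


@pytest.fixture
def heavy_chain_graph():
    """Four-atom heavy chain with a single 360-degree torsion entry."""
    return make_graph(
        ["C", "N", "O", "S"], [(0, 1, 1), (1, 2, 1), (2, 3, 1)]
    )


@pytest.fixture
def ethane_graph():
    """A-B with three identical terminal substituents on each side."""
    bonds = [(0, 1, 1)] + [(0, i, 1) for i in (2, 3, 4)] + [
        (1, i, 1) for i in (5, 6, 7)
    ]
    return make_graph(["C", "C"] + ["H"] * 6, bonds)


@pytest.fixture
def benzene_graph():
    bonds = [(i, (i + 1) % 6, 4) for i in range(6)] + [
        (i, i + 6, 1) for i in range(6)
    ]
    return make_graph(["C"] * 6 + ["H"] * 6, bonds, title="benzene")


@pytest.fixture
def keto_enol_graphs():
    """Same formula, different bond orders / H placement: two tautomers."""
    # keto: H3C-CH(=O) ; enol: H2C=CH-OH
    elements = ["C", "C", "O", "H", "H", "H", "H"]
    keto = make_graph(
        elements,
        [(0, 1, 1), (1, 2, 2), (0, 3, 1), (0, 4, 1), (0, 5, 1), (1, 6, 1)],
    )
    enol = make_graph(
        elements,
        [(0, 1, 2), (1, 2, 1), (0, 3, 1), (0, 4, 1), (2, 5, 1), (1, 6, 1)],
    )
    return keto, enol


def random_heavy_graph(rng, n_atoms, elements=("C", "N", "O")):
    """Random connected heavy-atom-only graph (tree plus optional extra edge)."""
    syms = [str(rng.choice(elements)) for _ in range(n_atoms)]
    bonds = []
    for i in range(1, n_atoms):
        parent = int(rng.integers(0, i))
        bonds.append((parent, i, int(rng.choice([1, 1, 1, 2]))))
    if n_atoms >= 4 and rng.random() < 0.4:
        existing = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        i, j = sorted(rng.choice(n_atoms, size=2, replace=False))
        if (int(i), int(j)) not in existing:
            bonds.append((int(i), int(j), 1))
    return make_graph(syms, bonds)


def brute_force_automorphisms(graph):
    """Oracle: all label/adjacency-preserving permutations by exhaustion.

    Iterates the product of within-element-class permutations, so it is only
    usable on small graphs.
    """
    n = graph.n_atoms
    labels = [(a[0], a[1]) for a in graph.atoms]
    classes = {}
    for i, lbl in enumerate(labels):
        classes.setdefault(lbl, []).append(i)
    adjacency = {}
    for i, j, o in graph.bonds:
        adjacency[(min(i, j), max(i, j))] = o
    out = []
    class_items = sorted(classes.items())
    for combo in itertools.product(
        *[itertools.permutations(members) for _lbl, members in class_items]
    ):
        perm = [0] * n
        for (_lbl, members), assigned in zip(class_items, combo):
            for src, dst in zip(members, assigned):
                perm[src] = dst
        ok = True
        for (i, j), o in adjacency.items():
            key = (min(perm[i], perm[j]), max(perm[i], perm[j]))
            if adjacency.get(key) != o:
                ok = False
                break
        if ok:
            out.append(tuple(perm))
    return out


def random_conformer(rng, n_atoms, energy=0.0, source="QM"):
    return Conformer(rng.normal(scale=2.0, size=(n_atoms, 3)), energy, source)


@pytest.fixture(scope="session")
def small_benchmark():
    """A compact seeded benchmark reused by several test modules."""
    config = SynthConfig(
        seed=42,
        n_molecules=15,
        conformers=(2, 5),
        tautomer_flip_rate=0.2,
        collapse_rate=0.05,
    )
    return generate_benchmark(config)
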
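"""Shared fixtures: simulated datasets and random additive tree metrics."""

from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from ribogap import simulate as sim
from ribogap.distance import DistanceMatrix
from ribogap.phylonet import Tree


def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> Tree:
    """Random unrooted binary tree with uniform branch lengths in [0.1, 2]."""
    nodes = list(range(n_leaves))
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}
    nid = n_leaves
    rnd = random.Random(int(rng.integers(1 << 30)))

    def connect(a: int, b: int, w: float):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    while len(nodes) > 2:
        a, b = rnd.sample(nodes, 2)
        nodes.remove(a)
        nodes.remove(b)
        connect(a, nid, float(rng.uniform(0.1, 2)))
        connect(b, nid, float(rng.uniform(0.1, 2)))
        nodes.append(nid)
        nid += 1
    connect(nodes[0], nodes[1], float(rng.uniform(0.1, 2)))
    return Tree(adj, {i: f"t{i:02d}" for i in range(n_leaves)})


def box_metric(w1: float, w2: float, trivial: dict[int, float] | None = None):
    """4-taxon metric that is the sum of the two incompatible splits
    ab|cd (weight w1) and ad|bc (weight w2) plus optional leaf splits."""
    import itertools

    labels = ["a", "b", "c", "d"]
    trivial = trivial or {}
    D = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        d = trivial.get(i, 0.0) + trivial.get(j, 0.0)
        if (i < 2) != (j < 2):
            d += w1
        if (i in (0, 3)) != (j in (0, 3)):
            d += w2
        D[i, j] = D[j, i] = d
    return DistanceMatrix.from_square(labels, D)


@pytest.fixture(scope="session")
def birth_death_dataset() -> sim.SimulatedDataset:
    return sim.simulate_dataset(sim.birth_death_config(1))


@pytest.fixture(scope="session")
def homogenized_dataset() -> sim.SimulatedDataset:
    return sim.simulate_dataset(sim.homogenized_config(1))


@pytest.fixture(scope="session")
def admixed_dataset() -> sim.SimulatedDataset:
    return sim.simulate_dataset(sim.admixed_config(1))
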
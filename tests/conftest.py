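import itertools

import numpy as np
import pytest

from dagclimb.dag import DirectedGraph
from dagclimb.scoring import StandardizedDataset, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_dag(rng, nodes, p_edge=0.4):
    """Random DAG: orient a random node order, keep each forward pair w.p. p_edge."""
    order = list(rng.permutation(nodes))
    edges = [
        (order[i], order[j])
        for i in range(len(order))
        for j in range(i + 1, len(order))
        if rng.random() < p_edge
    ]
    return DirectedGraph(nodes, edges)


def random_dataset(rng, columns, n=200):
    """Standardized dataset of correlated Gaussian columns."""
    p = len(columns)
    mix = rng.normal(size=(p, p)) / np.sqrt(p)
    raw = rng.normal(size=(n, p)) @ mix + rng.normal(size=(n, p))
    return standardize(raw, columns)


def all_dags(nodes):
    """Every DAG over ``nodes`` (exhaustive; keep len(nodes) <= 3ish)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in itertools.product([False, True], repeat=len(pairs)):
        edges = [e for e, on in zip(pairs, mask) if on]
        try:
            yield DirectedGraph(nodes, edges)
        except Exception:
            continue


@pytest.fixture
def chain_dataset(rng):
    """n=2000 linear chain a -> b -> c with coefficient 0.8, plus truth."""
    n = 2000
    a = rng.normal(size=n)
    b = 0.8 * a + rng.normal(size=n) * np.sqrt(1 - 0.64)
    c = 0.8 * b + rng.normal(size=n) * np.sqrt(1 - 0.64)
    return standardize(np.column_stack([a, b, c]), ["a", "b", "c"])
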
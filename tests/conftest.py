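"""Shared fixtures: the five-protein worked example and random generators.

The worked example is a predicted complex {A,B,C,D,E} over a four-point
cycle with activities A:{1,2}, B:{2,3,4}, C:{1}, D:{4}, E:{1,2} and
edges A-C, A-E, C-E, A-B, B-E, C-D.  Splitting yields {A,C,E}@t1,
{A,B,E}@t2, {B}@t3, {B}@t4, {D}@t4, and assembling at T=0.6 produces the
single refined complex {A,B,C,E} with D discarded.
"""

import networkx as nx
import numpy as np
import pytest

from jitrefine.activity import ActivityTable
from jitrefine.io import ComplexCatalog


@pytest.fixture
def worked_activity() -> ActivityTable:
    return ActivityTable(
        active={"A": {1, 2}, "B": {2, 3, 4}, "C": {1}, "D": {4}, "E": {1, 2}},
        n=4,
    )


@pytest.fixture
def worked_network() -> nx.Graph:
    return nx.Graph([("A", "C"), ("A", "E"), ("C", "E"), ("A", "B"), ("B", "E"), ("C", "D")])


@pytest.fixture
def worked_complex() -> frozenset:
    return frozenset("ABCDE")


@pytest.fixture
def worked_catalog(worked_complex) -> ComplexCatalog:
    return ComplexCatalog([worked_complex], label="worked-example")


def random_activity_table(rng: np.random.Generator, proteins, n: int,
                          p_wildcard: float = 0.15) -> ActivityTable:
    """Random activity: each protein gets a nonempty subset of 1..n, or {0}."""
    table = {}
    for p in proteins:
        if rng.random() < p_wildcard:
            table[p] = frozenset({0})
        else:
            k = int(rng.integers(1, n + 1))
            table[p] = frozenset(int(t) for t in rng.choice(np.arange(1, n + 1), size=k,
                                                            replace=False))
    return ActivityTable(active=table, n=n)
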
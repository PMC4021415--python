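from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from icod import SeedGeneSet, extract_subnetwork


@pytest.fixture
def triangle_tail() -> nx.Graph:
    """Triangle A-B-C plus a pendant edge C-D."""
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.Graph([("A", "B"), ("B", "C")])


@pytest.fixture
def star4() -> nx.Graph:
    return nx.Graph([("S", "X"), ("S", "Y"), ("S", "Z")])


def make_subnet(net: nx.Graph, label: str, members: set[str], seeds: set[str] | None = None):
    """Build a DiseaseSubnetwork with an explicit member set (test shortcut)."""
    from icod.subnetwork import DiseaseSubnetwork

    seeds = seeds if seeds is not None else members
    return DiseaseSubnetwork(
        label=label,
        seed_genes_used=frozenset(seeds),
        members=frozenset(members),
        graph=net.subgraph(members).copy(),
    )


def random_connected_graph(rng: np.random.Generator, n_max: int = 12) -> nx.Graph:
    """Small random graph (possibly disconnected) with string node labels."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})


@pytest.fixture
def subnet_factory():
    return make_subnet
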
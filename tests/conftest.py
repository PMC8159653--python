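"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive quantities from first principles (Floyd–Warshall
distances, subset-enumeration cliques, direct formula evaluation) so the
package's BFS/Bron–Kerbosch/vectorised paths are checked against code that
shares nothing with them.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from netprox.graph_core import PPINetwork


@pytest.fixture
def path_abc() -> PPINetwork:
    """The 3-node path a–b–c."""
    return PPINetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def path_abc_plus_d() -> PPINetwork:
    """Path a–b–c plus an isolated node d."""
    return PPINetwork.from_edges([("a", "b"), ("b", "c")], nodes=["d"])


def floyd_warshall(net: PPINetwork) -> dict[tuple[str, str], float]:
    """Brute-force all-pairs distances; math.inf for unreachable pairs."""
    nodes = sorted(net.nodes)
    dist = {(u, v): (0 if u == v else math.inf) for u in nodes for v in nodes}
    for a, b in net.edges():
        dist[(a, b)] = dist[(b, a)] = 1
    for k in nodes:
        for i in nodes:
            for j in nodes:
                via = dist[(i, k)] + dist[(k, j)]
                if via < dist[(i, j)]:
                    dist[(i, j)] = via
    return dist


def brute_maximal_cliques(net: PPINetwork) -> list[frozenset[str]]:
    """All maximal cliques by exhaustive subset enumeration (n <= ~14)."""
    nodes = sorted(net.nodes)
    adj = {n: set(net.graph.neighbors(n)) for n in nodes}
    cliques = []
    for r in range(1, len(nodes) + 1):
        for comb in itertools.combinations(nodes, r):
            if all(v in adj[u] for u, v in itertools.combinations(comb, 2)):
                cliques.append(frozenset(comb))
    return [c for c in cliques if not any(c < d for d in cliques)]


def brute_mcc(net: PPINetwork) -> dict[str, int]:
    scores = {n: 0 for n in net.nodes}
    for c in brute_maximal_cliques(net):
        w = math.factorial(len(c) - 1)
        for n in c:
            scores[n] += w
    return scores


def random_graph(rng: np.random.Generator, n: int, p: float,
                 connected: bool = False) -> PPINetwork:
    """Erdos–Renyi-style random graph over string node names."""
    nodes = [f"N{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    if connected:
        # spanning chain over a random permutation guarantees connectivity
        perm = rng.permutation(n)
        edges += [(nodes[perm[i]], nodes[perm[i + 1]]) for i in range(n - 1)]
    return PPINetwork.from_edges(edges, nodes=nodes)
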
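"""Maximal clique centrality (MCC) hub scoring.

MCC(v) = Σ over maximal cliques C containing v of (|C| − 1)!.  Nodes that
sit in many large cliques score highest; an isolated node owns its
singleton maximal clique and scores 0! = 1, so every node has a score.
Clique enumeration is Bron–Kerbosch with pivoting (networkx
``find_cliques``), output-sensitive but exponential in the worst case,
hence a configurable node cap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .genesets import GeneSet
from .graph_core import PPINetwork

logger = logging.getLogger(__name__)

DEFAULT_NODE_CAP = 10_000


@dataclass
class HubScoreTable:
    """Node → MCC score with dense descending ranks and top-k selection."""

    frame: pd.DataFrame  # columns: node, mcc, rank, selected

    def score(self, node: str) -> int:
        return int(self.frame.set_index("node").loc[node, "mcc"])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def maximal_cliques(
    net: PPINetwork, node_cap: int = DEFAULT_NODE_CAP
) -> list[frozenset[str]]:
    """All maximal cliques; isolated nodes appear as singleton cliques."""
    if net.n_nodes > node_cap:
        raise ValueError(
            f"network has {net.n_nodes} nodes > cap {node_cap}; restrict to "
            "the largest connected component or raise node_cap"
        )
    return [frozenset(c) for c in nx.find_cliques(net.graph)]


def mcc_scores(net: PPINetwork, node_cap: int = DEFAULT_NODE_CAP) -> HubScoreTable:
    """MCC score every node; ranks are dense over descending score."""
    scores: dict[str, int] = {n: 0 for n in net.graph.nodes}
    for clique in maximal_cliques(net, node_cap=node_cap):
        w = math.factorial(len(clique) - 1)
        for n in clique:
            scores[n] += w
    df = pd.DataFrame(
        sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["node", "mcc"],
    )
    df["rank"] = df["mcc"].rank(method="dense", ascending=False).astype(int)
    df["selected"] = False
    return HubScoreTable(df)


def top_k_hubs(table: HubScoreTable, k: int) -> GeneSet:
    """The k highest-MCC nodes; boundary ties are all included (logged).

    Mutates ``table.frame['selected']`` to mark membership.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    df = table.frame
    if k > len(df):
        raise ValueError(f"k={k} exceeds node count {len(df)}")
    cutoff = df["mcc"].iloc[k - 1]
    selected = df["mcc"] >= cutoff
    if selected.sum() > k:
        logger.info(
            "top_k_hubs: tie at rank %d expanded selection from %d to %d nodes",
            k,
            k,
            int(selected.sum()),
        )
    df["selected"] = selected
    return GeneSet.from_symbols(
        f"top{k}_hubs", df.loc[selected, "node"].tolist(), provenance="G_P"
    )
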
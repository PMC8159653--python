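"""Protein–protein interaction graph model, I/O and shortest-path services.

The background network for all set-distance computations is an undirected,
unweighted graph of gene/protein symbols.  Edge confidence scores (STRING's
"combined score") are used only to threshold edges at read time; distances
are always plain hop counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)


class _Unreachable:
    """Sentinel for node pairs with no connecting path.

    Deliberately not a number: callers must decide how to treat unreachable
    pairs (drop, error, ...) instead of silently averaging an infinity.
    """

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "UNREACHABLE"


UNREACHABLE = _Unreachable()


def normalize_symbol(symbol: str) -> str:
    """Whitespace-trim and upper-case a gene/protein identifier.

    Source tables mix case freely (``Cyp2c9`` vs ``CYP2C9``); all ingest
    paths funnel through this.
    """
    return str(symbol).strip().upper()


@dataclass
class PPINetwork:
    """Undirected PPI graph: no self-loops, no duplicate edges.

    Wraps a :class:`networkx.Graph`; node identifiers are case-normalized
    gene symbols.  Edge attribute ``score`` (confidence in [0, 1]) is kept
    when present but never used as a weight.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
    ) -> "PPINetwork":
        g = nx.Graph()
        for n in nodes:
            g.add_node(normalize_symbol(n))
        for a, b in edges:
            a, b = normalize_symbol(a), normalize_symbol(b)
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        """Canonical sorted edge list (each pair sorted, rows sorted)."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def __contains__(self, node: str) -> bool:
        return normalize_symbol(node) in self.graph


def read_edge_list(
    path: str | Path,
    score_column: str | None = None,
    min_score: float = 0.0,
) -> PPINetwork:
    """Read a TSV edge list into a :class:`PPINetwork`.

    The first two columns are node identifiers.  If ``score_column`` is
    given, edges whose score falls below ``min_score`` are dropped.  Scores
    greater than 1 are assumed to be on STRING's 0–1000 scale and divided
    by 1000 before thresholding.  Self-loops and duplicate edges are
    collapsed with a logged count.  A header row is detected when a named
    score column must be located, or when the third column of the first
    row is non-numeric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")

    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: malformed row (expected >=2 tab-separated "
                    f"columns, got {len(parts)})"
                )
            rows.append(parts)
    if not rows:
        raise ValueError(f"{path}: empty edge list")

    score_idx: int | None = None
    header = rows[0]
    has_header = False
    if score_column is not None:
        if score_column in header:
            has_header = True
            score_idx = header.index(score_column)
        else:
            # headerless file: score_column may name a positional 3rd column
            try:
                float(header[2]) if len(header) > 2 else None
            except (ValueError, IndexError):
                pass
            if len(header) > 2 and _is_number(header[2]):
                score_idx = 2
            else:
                raise ValueError(
                    f"{path}: score column {score_column!r} not found in header "
                    f"{header!r}"
                )
    else:
        # drop an apparent header (non-numeric 3rd col, or repeated in no row)
        if len(header) >= 3 and not _is_number(header[2]):
            has_header = True

    data = rows[1:] if has_header else rows

    g = nx.Graph()
    n_self, n_dup, n_below = 0, 0, 0
    for lineno, parts in enumerate(data, start=2 if has_header else 1):
        a, b = normalize_symbol(parts[0]), normalize_symbol(parts[1])
        g.add_node(a)  # endpoints stay as nodes even when the edge is dropped
        if a != b:
            g.add_node(b)
        score: float | None = None
        if score_idx is not None:
            try:
                score = float(parts[score_idx])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse score from {parts!r}"
                ) from exc
            if score > 1:
                score = score / 1000.0  # STRING 0-1000 dialect
            if score < min_score:
                n_below += 1
                continue
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        if score is not None:
            g.add_edge(a, b, score=score)
        else:
            g.add_edge(a, b)
    if n_self or n_dup or n_below:
        logger.info(
            "read %s: dropped %d self-loops, %d duplicates, %d edges below "
            "min_score=%g",
            path,
            n_self,
            n_dup,
            n_below,
            min_score,
        )
    return PPINetwork(g)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the canonical 2-column TSV edge list (sorted, deduplicated)."""
    with open(path, "w") as fh:
        for a, b in net.edges():
            fh.write(f"{a}\t{b}\n")


def write_node_table(net: PPINetwork, path: str | Path) -> None:
    """Write a node table (node, degree) TSV, e.g. for Cytoscape import."""
    with open(path, "w") as fh:
        fh.write("node\tdegree\n")
        for n in sorted(net.graph.nodes):
            fh.write(f"{n}\t{net.graph.degree[n]}\n")


def largest_connected_component(net: PPINetwork) -> PPINetwork:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken toward the component containing the
    lexicographically smallest node, so the result is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("network is empty")
    comps = list(nx.connected_components(net.graph))
    best = sorted(comps, key=lambda c: (-len(c), min(c)))[0]
    return PPINetwork(net.graph.subgraph(best).copy())


class DistanceOracle:
    """Hop-count distances from a set of source nodes to all nodes.

    ``distance(a, b)`` returns a non-negative int, or :data:`UNREACHABLE`
    when no path exists.  Rows exist for the requested sources only; lookups
    are symmetric when both endpoints are sources.
    """

    def __init__(self, net: PPINetwork, rows: Mapping[str, Mapping[str, int]]):
        self.network = net
        self._rows = {k: dict(v) for k, v in rows.items()}

    @property
    def sources(self) -> set[str]:
        return set(self._rows)

    def distance(self, a: str, b: str):
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a in self._rows:
            return self._rows[a].get(b, UNREACHABLE)
        if b in self._rows:
            return self._rows[b].get(a, UNREACHABLE)
        raise KeyError(f"neither {a!r} nor {b!r} is an oracle source")


def shortest_paths_from(net: PPINetwork, sources: Iterable[str]) -> DistanceOracle:
    """BFS hop counts from each source to every reachable node.

    Raises if any source is not a network node, listing the offenders.
    """
    srcs = {normalize_symbol(s) for s in sources}
    missing = srcs - net.nodes
    if missing:
        raise KeyError(f"sources not in network: {sorted(missing)}")
    rows = {
        s: dict(nx.single_source_shortest_path_length(net.graph, s)) for s in srcs
    }
    return DistanceOracle(net, rows)
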
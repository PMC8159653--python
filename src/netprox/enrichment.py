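"""Hypergeometric over-representation analysis against GMT collections.

For a query of n genes drawn from a universe of N, a term with K member
genes and k of them in the query gets the upper-tail p-value
P(X ≥ k) with X ~ Hypergeometric(N, K, n).  BH adjustment runs across all
tested terms; a term is *selected* when p_raw < alpha and q < qmax (both
default 0.05).  The universe defaults to all genes in the collection plus
the query, since over-representation backgrounds are rarely stated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .genesets import GeneSet
from .graph_core import normalize_symbol

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term: str
    description: str
    k: int  # overlap
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    p_raw: float
    q: float
    selected: bool
    members: frozenset[str]


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file: term<TAB>description<TAB>gene1<TAB>gene2..."""
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT rows need term, description, >=1 gene"
                )
            term, desc, genes = parts[0], parts[1], parts[2:]
            out[term] = (desc, frozenset(normalize_symbol(g) for g in genes if g))
    return out


def write_gmt(collection: Mapping[str, tuple[str, frozenset[str]]],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(collection):
            desc, genes = collection[term]
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def hypergeom_enrich(
    query: GeneSet,
    collection: Mapping[str, tuple[str, frozenset[str]]],
    universe: GeneSet | None = None,
    alpha: float = 0.05,
    qmax: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of ``query`` against every GMT term."""
    if universe is None:
        uni = frozenset().union(*(g for _, g in collection.values()), query.members) \
            if collection else query.members
    else:
        uni = universe.members
        if not uni:
            raise ValueError("universe is empty")
    stray = query.members - uni
    if stray:
        logger.warning(
            "%d query genes outside the universe dropped: %s",
            len(stray), sorted(stray)[:5],
        )
    q_genes = query.members & uni
    N, n = len(uni), len(q_genes)
    if N == 0:
        raise ValueError("universe is empty")

    results: list[EnrichmentResult] = []
    for term in sorted(collection):
        desc, genes = collection[term]
        term_genes = genes & uni
        K = len(term_genes)
        if K == 0:
            continue
        overlap = term_genes & q_genes
        k = len(overlap)
        # P(X >= k) = sf(k - 1); k = 0 gives 1 by convention
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(
            EnrichmentResult(term, desc, k, K, n, N, min(p, 1.0), 1.0, False,
                             frozenset(overlap))
        )
    if results:
        qvals = bh_adjust([r.p_raw for r in results])
        for r, qv in zip(results, qvals):
            r.q = float(qv)
            r.selected = r.p_raw < alpha and r.q < qmax
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "description": r.description,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "q": r.q,
                "selected": r.selected,
                "members": ",".join(sorted(r.members)),
            }
            for r in results
        ]
    )


def term_gene_network(
    results: list[EnrichmentResult],
    targets: Mapping[str, GeneSet],
) -> pd.DataFrame:
    """Compound–target–pathway edge table for Cytoscape import.

    Compound→target edges are solid; target→term edges (for selected or all
    supplied results) are dashed, flagged in the ``edge_type`` column.  A
    ``degree`` table can be derived by value-counting the node columns.
    """
    if not results:
        raise ValueError("no enrichment results supplied")
    rows: list[dict] = []
    term_members = {r.term: r.members for r in results}
    for comp in sorted(targets):
        for tgt in sorted(targets[comp].members):
            rows.append(
                {"source": comp, "target": tgt, "edge_type": "compound-target",
                 "style": "solid"}
            )
    linked_targets = {t for gs in targets.values() for t in gs.members}
    for term in sorted(term_members):
        for tgt in sorted(term_members[term] & linked_targets):
            rows.append(
                {"source": tgt, "target": term, "edge_type": "target-pathway",
                 "style": "dashed"}
            )
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "style"])


def node_degrees(edge_table: pd.DataFrame) -> pd.Series:
    """Node degree counts over a term_gene_network edge table."""
    return pd.concat([edge_table["source"], edge_table["target"]]).value_counts()
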
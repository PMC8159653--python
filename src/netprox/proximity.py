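"""Topological set distances and the drug–disease separation score.

Given an ingredient's target set *A* and a key disease gene set *B* on a
background PPI network, three set distances summarise their topological
relationship (d(a, b) is the unweighted shortest-path hop count):

mean shortest distance
    ⟨d_AB^S⟩ = (1 / ‖A‖‖B‖) Σ_{a∈A, b∈B} d(a, b)

closest distance
    ⟨d_AB^C⟩ = (1 / (‖A‖+‖B‖)) [ Σ_{a∈A} min_{b∈B} d(a, b)
                                 + Σ_{b∈B} min_{a∈A} d(a, b) ]

kernel distance
    ⟨d_AB^K⟩ = −(1 / (‖A‖+‖B‖)) [ Σ_{a∈A} ln( Σ_{b∈B} e^{−(d(a,b)+1)} / ‖B‖ )
                                  + Σ_{b∈B} ln( Σ_{a∈A} e^{−(d(a,b)+1)} / ‖A‖ ) ]

The separation (proximity) score compares the between-set mean with the
two within-set means:

    S_AB = ⟨d_AB^S⟩ − (⟨d_AA^S⟩ + ⟨d_BB^S⟩) / 2

S_AB < 0 marks the ingredient's targets as topologically close to the key
set — the "interference" call.  Unreachable node pairs are dropped from
every mean, with the dropped count recorded per ingredient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .genesets import GeneSet
from .graph_core import DistanceOracle, PPINetwork, UNREACHABLE, shortest_paths_from

logger = logging.getLogger(__name__)

WithinSetConvention = Literal["allpairs", "nearest"]


@dataclass
class ProximityRow:
    """Per-ingredient proximity record."""

    ingredient_id: str
    n_A: int
    n_B: int
    d_S: float
    d_C: float
    d_K: float
    d_AA: float
    d_BB: float
    S_P: float
    interferes: bool
    n_dropped: int


def _mapped(s: GeneSet, net: PPINetwork) -> list[str]:
    return sorted(s.members & net.nodes)


def mean_shortest_distance(
    oracle: DistanceOracle, A: GeneSet, B: GeneSet
) -> tuple[float, int]:
    """All-pairs mean hop distance ⟨d_AB^S⟩.

    Returns ``(mean, n_dropped)`` where ``n_dropped`` counts unreachable
    (a, b) pairs excluded from numerator and denominator alike.
    """
    a_nodes = _mapped(A, oracle.network)
    b_nodes = _mapped(B, oracle.network)
    if not a_nodes or not b_nodes:
        raise ValueError("a gene set maps to zero network nodes")
    total, n, dropped = 0.0, 0, 0
    for a in a_nodes:
        for b in b_nodes:
            d = oracle.distance(a, b)
            if d is UNREACHABLE:
                dropped += 1
            else:
                total += d
                n += 1
    if n == 0:
        raise ValueError("no finite distances between the two sets")
    return total / n, dropped


def closest_distance(
    oracle: DistanceOracle, A: GeneSet, B: GeneSet
) -> tuple[float, int]:
    """Closest-member distance ⟨d_AB^C⟩: mean over each node's nearest
    partner in the opposite set, averaged over ‖A‖+‖B‖ terms.

    A node with no reachable partner contributes no term (dropped, counted).
    """
    a_nodes = _mapped(A, oracle.network)
    b_nodes = _mapped(B, oracle.network)
    if not a_nodes or not b_nodes:
        raise ValueError("a gene set maps to zero network nodes")
    total, n, dropped = 0.0, 0, 0
    for side_from, side_to in ((a_nodes, b_nodes), (b_nodes, a_nodes)):
        for u in side_from:
            ds = [
                d
                for v in side_to
                if (d := oracle.distance(u, v)) is not UNREACHABLE
            ]
            if not ds:
                dropped += 1
                continue
            total += min(ds)
            n += 1
    if n == 0:
        raise ValueError("no finite distances between the two sets")
    return total / n, dropped


def kernel_distance(oracle: DistanceOracle, A: GeneSet, B: GeneSet) -> float:
    """Kernel (exponentially down-weighted) distance ⟨d_AB^K⟩.

    Each node contributes −ln of the mean of e^{−(d+1)} over the opposite
    set; unreachable pairs contribute e^{−∞} = 0 inside the inner sum.  A
    node unreachable from the *whole* opposite set makes the inner sum 0
    and is an error, because ln 0 is undefined.
    """
    a_nodes = _mapped(A, oracle.network)
    b_nodes = _mapped(B, oracle.network)
    if not a_nodes or not b_nodes:
        raise ValueError("a gene set maps to zero network nodes")
    total = 0.0
    for side_from, side_to in ((a_nodes, b_nodes), (b_nodes, a_nodes)):
        for u in side_from:
            inner = 0.0
            for v in side_to:
                d = oracle.distance(u, v)
                if d is not UNREACHABLE:
                    inner += math.exp(-(d + 1))
            if inner == 0.0:
                raise ValueError(
                    f"node {u!r} unreachable from the entire opposite set"
                )
            total += math.log(inner / len(side_to))
    return -total / (len(a_nodes) + len(b_nodes))


def within_set_distance(
    oracle: DistanceOracle,
    A: GeneSet,
    convention: WithinSetConvention = "allpairs",
) -> tuple[float, int]:
    """Within-set mean distance ⟨d_AA^S⟩.

    ``allpairs`` (default) applies the all-pairs mean with both arguments
    equal, so self-pairs (d = 0) are included.  ``nearest`` averages each
    node's distance to its nearest *other* member; a singleton set is
    defined to have d_AA = 0 under this convention.
    """
    if convention == "allpairs":
        return mean_shortest_distance(oracle, A, A)
    a_nodes = _mapped(A, oracle.network)
    if not a_nodes:
        raise ValueError("gene set maps to zero network nodes")
    if len(a_nodes) == 1:
        return 0.0, 0
    total, n, dropped = 0.0, 0, 0
    for u in a_nodes:
        ds = [
            d
            for v in a_nodes
            if v != u and (d := oracle.distance(u, v)) is not UNREACHABLE
        ]
        if not ds:
            dropped += 1
            continue
        total += min(ds)
        n += 1
    if n == 0:
        raise ValueError("no finite within-set distances")
    return total / n, dropped


def separation_score(d_S: float, d_AA: float, d_BB: float) -> float:
    """S_AB = d_S − (d_AA + d_BB)/2; negative means topological proximity."""
    for name, v in (("d_S", d_S), ("d_AA", d_AA), ("d_BB", d_BB)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite: {v!r}")
    return d_S - (d_AA + d_BB) / 2.0


def proximity_table(
    net: PPINetwork,
    targets: Mapping[str, GeneSet],
    key_set: GeneSet,
    within_set: WithinSetConvention = "allpairs",
) -> list[ProximityRow]:
    """Score every ingredient's target set against the key gene set.

    Ingredients whose targets all fall outside the network are skipped with
    a logged warning.  Rows come back sorted by S_P ascending (most
    proximal first).
    """
    b_nodes = key_set.members & net.nodes
    if not b_nodes:
        raise ValueError("key set maps to zero network nodes")
    b_set = GeneSet("B", frozenset(b_nodes), key_set.provenance)

    oracle_b = shortest_paths_from(net, b_nodes)
    d_BB, _ = within_set_distance(oracle_b, b_set, within_set)

    rows: list[ProximityRow] = []
    for ing_id, tset in targets.items():
        a_nodes = tset.members & net.nodes
        if not a_nodes:
            logger.warning(
                "ingredient %s: no targets map into the network; skipped", ing_id
            )
            continue
        a_set = GeneSet("A", frozenset(a_nodes))
        oracle = shortest_paths_from(net, a_nodes | b_nodes)
        d_S, drop_s = mean_shortest_distance(oracle, a_set, b_set)
        d_C, drop_c = closest_distance(oracle, a_set, b_set)
        d_K = kernel_distance(oracle, a_set, b_set)
        d_AA, _ = within_set_distance(oracle, a_set, within_set)
        s_p = separation_score(d_S, d_AA, d_BB)
        rows.append(
            ProximityRow(
                ingredient_id=ing_id,
                n_A=len(a_nodes),
                n_B=len(b_nodes),
                d_S=d_S,
                d_C=d_C,
                d_K=d_K,
                d_AA=d_AA,
                d_BB=d_BB,
                S_P=s_p,
                interferes=s_p < 0,
                n_dropped=drop_s,
            )
        )
    rows.sort(key=lambda r: (r.S_P, r.ingredient_id))
    return rows


def proximity_frame(rows: list[ProximityRow]) -> pd.DataFrame:
    """Proximity rows as a DataFrame in the export column order."""
    return pd.DataFrame(
        [
            {
                "ingredient_id": r.ingredient_id,
                "n_A": r.n_A,
                "n_B": r.n_B,
                "d_S": r.d_S,
                "d_C": r.d_C,
                "d_K": r.d_K,
                "d_AA": r.d_AA,
                "d_BB": r.d_BB,
                "S_P": r.S_P,
                "interferes": r.interferes,
                "n_dropped": r.n_dropped,
            }
            for r in rows
        ]
    )


def write_proximity_table(rows: list[ProximityRow], path: str | Path) -> None:
    """Write the proximity TSV, floats rounded to 2 decimals for export."""
    df = proximity_frame(rows)
    for col in ("d_S", "d_C", "d_K", "d_AA", "d_BB", "S_P"):
        df[col] = df[col].round(2)
    df.to_csv(path, sep="\t", index=False)


def read_targets_table(path: str | Path) -> dict[str, GeneSet]:
    """Read an ingredient→target TSV (columns ingredient_id, target_symbol).

    Optional provenance columns (``precision``, ``max_tc``, ``probability``,
    ``combined_score``) are ignored here; :mod:`netprox.screening` applies
    the prediction-server thresholds when those columns are present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected >=2 columns")
    ing_col, tgt_col = df.columns[0], df.columns[1]
    out: dict[str, GeneSet] = {}
    for ing, sub in df.groupby(ing_col, sort=True):
        out[str(ing)] = GeneSet.from_symbols(str(ing), sub[tgt_col].tolist())
    return out
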
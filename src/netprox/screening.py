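"""Ingredient-level ADMET screening and gene-set assembly logic.

Covers the pharmacokinetic filter on herbal-formula ingredients
(gastrointestinal absorption class and predicted oral bioavailability),
removal of ingredients without a PubChem CID, the key-set assembly
G_K = (G_D ∩ G_W) ∪ G_P, and the ingredient-target × disease-set
intersection that yields the directly-hit disease targets (G_YH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .genesets import GeneSet

logger = logging.getLogger(__name__)

# Prediction-server score cutoffs applied when provenance columns are present
SERVER_THRESHOLDS = {
    "precision": 80.0,     # HitPick precision, percent
    "max_tc": 0.9,         # SEA max Tanimoto coefficient
    "probability": 0.8,    # SwissTargetPrediction probability
    "combined_score": 0.8,  # STITCH combined score (fraction)
}


@dataclass
class IngredientRecord:
    """One ADMET row for a small-molecule ingredient."""

    mol_id: str
    name: str
    molecular_formula: str
    pubchem_cid: str | None
    gi_absorption: str  # "High" | "Low"
    bioavailability_pct: float

    def __post_init__(self) -> None:
        if self.gi_absorption not in ("High", "Low"):
            raise ValueError(
                f"{self.mol_id}: gi_absorption must be High or Low, "
                f"got {self.gi_absorption!r}"
            )
        if not 0 <= self.bioavailability_pct <= 100:
            raise ValueError(
                f"{self.mol_id}: bioavailability {self.bioavailability_pct} "
                "outside [0, 100]"
            )


def read_admet_table(path: str | Path) -> list[IngredientRecord]:
    """Read an ADMET TSV (mol_id, name, molecular_formula, pubchem_cid,
    gi_absorption, bioavailability_pct)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        cid = row.get("pubchem_cid")
        if pd.isna(cid) or str(cid).strip() == "":
            cid = None
        records.append(
            IngredientRecord(
                mol_id=str(row["mol_id"]),
                name=str(row["name"]),
                molecular_formula=str(row["molecular_formula"]),
                pubchem_cid=None if cid is None else str(cid),
                gi_absorption=str(row["gi_absorption"]),
                bioavailability_pct=float(row["bioavailability_pct"]),
            )
        )
    ids = [r.mol_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate mol_id in ADMET table")
    return records


def admet_filter(
    records: list[IngredientRecord],
    min_bioavail: float = 70.0,
    require_high_gi: bool = True,
) -> tuple[list[IngredientRecord], dict[str, int]]:
    """Filter ingredients on GI absorption and bioavailability.

    The bioavailability comparison is strict (> min_bioavail).  Returns the
    passing records and summary counts over the *input* records:
    n_total, n_high_gi, n_bioavail_gt_threshold.
    """
    counts = {
        "n_total": len(records),
        "n_high_gi": sum(r.gi_absorption == "High" for r in records),
        "n_bioavail_gt_threshold": sum(
            r.bioavailability_pct > min_bioavail for r in records
        ),
    }
    kept = [
        r
        for r in records
        if (not require_high_gi or r.gi_absorption == "High")
        and r.bioavailability_pct > min_bioavail
    ]
    return kept, counts


def drop_missing_cid(records: list[IngredientRecord]) -> list[IngredientRecord]:
    """Remove ingredients that could not be mapped to a PubChem CID."""
    kept = [r for r in records if r.pubchem_cid]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("dropped %d ingredients lacking a PubChem CID", n_dropped)
    if not kept and records:
        logger.warning("all ingredients lack a PubChem CID")
    return kept


def assemble_key_set(gd: GeneSet, gw: GeneSet, gp: GeneSet) -> GeneSet:
    """G_K = (G_D ∩ G_W) ∪ G_P — the key disease gene set."""
    return GeneSet("G_K", (gd.members & gw.members) | gp.members,
                   provenance="G_K")


def apply_server_thresholds(df: pd.DataFrame) -> pd.DataFrame:
    """Row-filter a target table on any present prediction-server columns.

    Absent columns mean the input was pre-filtered upstream; each present
    column is compared ≥ its standard cutoff (see SERVER_THRESHOLDS).
    """
    mask = pd.Series(True, index=df.index)
    for col, cutoff in SERVER_THRESHOLDS.items():
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            mask &= vals >= cutoff
    return df[mask]


def target_disease_intersect(
    targets: Mapping[str, GeneSet], disease: GeneSet
) -> tuple[GeneSet, dict[str, GeneSet], pd.DataFrame]:
    """Intersect the pooled ingredient targets with the disease gene set.

    Returns (G_YH, per-ingredient hit sets, bipartite degree table).  The
    degree table lists each ingredient's hit count and each hit target's
    ingredient count — the node degrees of the ingredient–target bipartite
    graph restricted to disease hits.
    """
    all_targets = frozenset().union(
        *(gs.members for gs in targets.values())
    ) if targets else frozenset()
    gyh = GeneSet("G_YH", all_targets & disease.members, provenance="G_YH")
    if not gyh.members:
        logger.info("no ingredient target overlaps the disease set")

    hits: dict[str, GeneSet] = {}
    rows = []
    target_count: dict[str, int] = {}
    for ing in sorted(targets):
        h = targets[ing].members & gyh.members
        hits[ing] = GeneSet(f"{ing}_hits", h)
        rows.append({"node": ing, "kind": "ingredient", "degree": len(h)})
        for t in h:
            target_count[t] = target_count.get(t, 0) + 1
    for t in sorted(gyh.members):
        rows.append({"node": t, "kind": "target",
                     "degree": target_count.get(t, 0)})
    degree_table = pd.DataFrame(rows, columns=["node", "kind", "degree"])
    return gyh, hits, degree_table


def bipartite_edge_table(targets: Mapping[str, GeneSet]) -> pd.DataFrame:
    """Ingredient–target edge list for Cytoscape import."""
    rows = [
        {"ingredient": ing, "target": t}
        for ing in sorted(targets)
        for t in sorted(targets[ing].members)
    ]
    return pd.DataFrame(rows, columns=["ingredient", "target"])
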
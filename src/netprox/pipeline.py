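"""End-to-end orchestration of the network-pharmacology workflow.

Stage order (each stage optional via ``RunConfig.stages``):

1. ``deg`` — differential expression per cohort; G_D is the cohort
   intersection (or the single cohort's DEG set).
2. ``modules`` — coexpression modules and module–trait correlation; G_W
   collects the most positively and most negatively trait-correlated
   module genes (intersected across cohorts when two are given).
3. ``network`` — read the background PPI, restrict to the largest
   connected component, score the G_HCC-induced subgraph with maximal
   clique centrality, select the top-k core set G_P.
4. ``survival`` — median-split log-rank screen over the key set
   G_K = (G_D ∩ G_W) ∪ G_P.
5. ``screening`` — ADMET filter and the target × disease intersection G_YH.
6. ``enrichment`` — over-representation of G_YH against a GMT collection.
7. ``proximity`` — the three set distances and separation score of every
   ingredient's targets against the key set.

Every run writes TSV tables plus ``manifest.json`` recording parameters,
input file hashes and package version; identical inputs give identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .comodules import (
    ModuleConfig,
    adjacency_matrix,
    assemble_gw,
    detect_modules,
    module_trait_correlation,
    select_soft_threshold,
    tom_similarity,
)
from .diffexpr import ExpressionMatrix, deg_sets, intersect_deg_sets, two_group_test
from .enrichment import enrichment_frame, hypergeom_enrich, read_gmt
from .genesets import GeneSet
from .graph_core import largest_connected_component, read_edge_list
from .hub_scoring import mcc_scores, top_k_hubs
from .proximity import proximity_table, read_targets_table, write_proximity_table
from .screening import (
    admet_filter,
    apply_server_thresholds,
    assemble_key_set,
    drop_missing_cid,
    read_admet_table,
    target_disease_intersect,
)
from .survival import read_clinical_table, survival_screen

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "deg", "modules", "network", "survival", "screening", "enrichment",
    "proximity",
)


@dataclass
class RunConfig:
    """Paths, stage toggles and stage parameters for a pipeline run.

    Thresholds default to the study's stated values: |log2FC| > 1.0 and
    BH q < 0.05 for DEGs, STRING combined score >= 0.9, minimum module
    size 50, tree-cut height 0.25, 25 core hub genes, enrichment
    p and q < 0.05, survival alpha 0.05, bioavailability > 70%.
    """

    out_dir: str = "netprox_run"
    stages: tuple[str, ...] = ALL_STAGES
    # inputs
    expression_path: str | None = None
    phenotype_path: str | None = None
    expression2_path: str | None = None
    phenotype2_path: str | None = None
    network_path: str | None = None
    clinical_path: str | None = None
    admet_path: str | None = None
    targets_path: str | None = None
    gmt_path: str | None = None
    keyset_path: str | None = None  # overrides the computed G_K for proximity
    # parameters
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    min_score: float = 0.9
    score_column: str | None = None
    beta: int | None = None  # None = automatic soft-threshold selection
    min_module_size: int = 50
    cut_height: float = 0.25
    hub_k: int = 25
    enrich_alpha: float = 0.05
    enrich_qmax: float = 0.05
    survival_alpha: float = 0.05
    min_bioavail: float = 70.0
    require_high_gi: bool = True
    within_set: str = "allpairs"
    seed: int | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in ("expression_path", "phenotype_path", "expression2_path",
                     "phenotype2_path", "network_path", "clinical_path",
                     "admet_path", "targets_path", "gmt_path", "keyset_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _cohort_deg(expr_path: str, phen_path: str, cfg: RunConfig
                ) -> tuple[pd.DataFrame, GeneSet, GeneSet, ExpressionMatrix]:
    mat = ExpressionMatrix.from_tsv(expr_path, phen_path)
    table = two_group_test(mat, lfc_threshold=cfg.lfc_threshold, alpha=cfg.alpha)
    up, down = deg_sets(table)
    return table, up, down, mat


def _cohort_modules(mat: ExpressionMatrix, cfg: RunConfig
                    ) -> tuple[pd.DataFrame, GeneSet, GeneSet]:
    """Module detection + trait correlation for one cohort.

    Returns the trait table and the (positive, negative) best-module gene
    sets; either may be empty when no module has that sign.
    """
    beta = cfg.beta or select_soft_threshold(mat)
    mconf = ModuleConfig(beta=beta, min_module_size=cfg.min_module_size,
                         cut_height=cfg.cut_height)
    tom = tom_similarity(adjacency_matrix(mat, beta))
    assign = detect_modules(tom, mconf, mat=mat)
    modules = assign.modules()
    empty = GeneSet("empty", frozenset())
    if not modules:
        return pd.DataFrame(columns=["module", "size", "r", "p"]), empty, empty
    trait = module_trait_correlation(assign, mat)
    pos_rows = trait[trait["r"] > 0]
    neg_rows = trait[trait["r"] < 0]
    pos = (modules[pos_rows.loc[pos_rows["r"].idxmax(), "module"]]
           if len(pos_rows) else empty)
    neg = (modules[neg_rows.loc[neg_rows["r"].idxmin(), "module"]]
           if len(neg_rows) else empty)
    return trait, pos, neg


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage failure aborts the run with a :class:`StageError` naming the
    stage, after writing a ``PARTIAL`` marker file into the run directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: list[str] = []
    gene_sets: dict[str, GeneSet] = {}
    mats: list[ExpressionMatrix] = []
    net_lcc = None
    targets = None

    manifest = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items()
                       if not k.endswith("_path") and k != "out_dir"},
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name in ("expression_path", "phenotype_path",
                         "expression2_path", "phenotype2_path", "network_path",
                         "clinical_path", "admet_path", "targets_path",
                         "gmt_path", "keyset_path")
            if (p := getattr(config, name)) is not None
        },
        "stages": list(config.stages),
    }

    def _save_set(gs: GeneSet, name: str) -> None:
        gene_sets[name] = gs
        gs.to_file(out / f"{name}.txt")

    try:
        stage = "deg"
        if "deg" in config.stages:
            table1, up1, down1, mat1 = _cohort_deg(
                config.expression_path, config.phenotype_path, config)
            table1.to_csv(out / "deg_cohort1.tsv", sep="\t")
            mats.append(mat1)
            set1 = up1.union(down1, name="deg1")
            if config.expression2_path:
                table2, up2, down2, mat2 = _cohort_deg(
                    config.expression2_path, config.phenotype2_path, config)
                table2.to_csv(out / "deg_cohort2.tsv", sep="\t")
                mats.append(mat2)
                gd = intersect_deg_sets(set1, up2.union(down2, name="deg2"))
            else:
                gd = GeneSet("G_D", set1.members, provenance="G_D")
            _save_set(gd, "G_D")
            summary.append(f"G_D: {len(gd)} genes")

        stage = "modules"
        if "modules" in config.stages:
            trait1, pos1, neg1 = _cohort_modules(mats[0], config)
            trait1.to_csv(out / "module_trait_cohort1.tsv", sep="\t",
                          index=False)
            if len(mats) > 1:
                trait2, pos2, neg2 = _cohort_modules(mats[1], config)
                trait2.to_csv(out / "module_trait_cohort2.tsv", sep="\t",
                              index=False)
                gw = assemble_gw(pos1, pos2, neg1, neg2)
            else:
                gw = GeneSet("G_W", pos1.members | neg1.members,
                             provenance="G_W")
            _save_set(gw, "G_W")
            summary.append(f"G_W: {len(gw)} genes")

        if "deg" in config.stages and "modules" in config.stages:
            ghcc = GeneSet("G_HCC",
                           gene_sets["G_D"].members | gene_sets["G_W"].members,
                           provenance="G_HCC")
            _save_set(ghcc, "G_HCC")
            summary.append(f"G_HCC (disease set): {len(ghcc)} genes")

        stage = "network"
        if "network" in config.stages:
            net = read_edge_list(config.network_path,
                                 score_column=config.score_column,
                                 min_score=config.min_score)
            net_lcc = largest_connected_component(net)
            summary.append(
                f"network: {net.n_nodes} nodes / {net.n_edges} edges, "
                f"LCC {net_lcc.n_nodes} nodes"
            )
            disease = gene_sets.get("G_HCC")
            sub_nodes = (disease.members & net_lcc.nodes
                         if disease else net_lcc.nodes)
            sub = type(net_lcc)(net_lcc.graph.subgraph(sub_nodes).copy())
            hubs = mcc_scores(sub)
            hubs.to_tsv(out / "hub_scores.tsv")
            k = min(config.hub_k, sub.n_nodes)
            gp = top_k_hubs(hubs, k)
            _save_set(GeneSet("G_P", gp.members, provenance="G_P"), "G_P")
            summary.append(f"G_P (core hubs, k={k}): {len(gp)} genes")

        if {"deg", "modules", "network"} <= set(config.stages):
            gk = assemble_key_set(gene_sets["G_D"], gene_sets["G_W"],
                                  gene_sets["G_P"])
            _save_set(gk, "G_K")
            summary.append(f"G_K (key set): {len(gk)} genes")

        stage = "survival"
        if "survival" in config.stages:
            clin = read_clinical_table(config.clinical_path)
            screen_set = gene_sets.get("G_K") or GeneSet.from_symbols(
                "all", mats[0].values.index)
            surv_set, surv_table = survival_screen(
                screen_set, mats[0], clin, alpha=config.survival_alpha)
            surv_table.to_csv(out / "survival_screen.tsv", sep="\t",
                              index=False)
            _save_set(surv_set, "survival_related")
            summary.append(f"survival-related genes: {len(surv_set)}")

        stage = "screening"
        if "screening" in config.stages:
            if config.admet_path:
                records = drop_missing_cid(read_admet_table(config.admet_path))
                kept, counts = admet_filter(
                    records, min_bioavail=config.min_bioavail,
                    require_high_gi=config.require_high_gi)
                pd.DataFrame([counts]).to_csv(out / "admet_counts.tsv",
                                              sep="\t", index=False)
                summary.append(
                    f"ADMET: {counts['n_total']} ingredients, "
                    f"{counts['n_high_gi']} high GI absorption, "
                    f"{counts['n_bioavail_gt_threshold']} with bioavailability "
                    f"> {config.min_bioavail:g}%"
                )
            if config.targets_path:
                raw = pd.read_csv(config.targets_path, sep="\t", dtype=str)
                filtered = apply_server_thresholds(raw)
                ing_col, tgt_col = filtered.columns[0], filtered.columns[1]
                targets = {
                    str(i): GeneSet.from_symbols(str(i), sub[tgt_col])
                    for i, sub in filtered.groupby(ing_col, sort=True)
                }
                disease = gene_sets.get("G_HCC")
                if disease:
                    gyh, hits, degrees = target_disease_intersect(
                        targets, disease)
                    _save_set(gyh, "G_YH")
                    degrees.to_csv(out / "target_degrees.tsv", sep="\t",
                                   index=False)
                    summary.append(
                        f"G_YH (direct disease targets): {len(gyh)} genes")

        stage = "enrichment"
        if "enrichment" in config.stages and config.gmt_path:
            collection = read_gmt(config.gmt_path)
            query = gene_sets.get("G_YH") or gene_sets.get("G_HCC")
            if query and len(query):
                results = hypergeom_enrich(
                    query, collection, alpha=config.enrich_alpha,
                    qmax=config.enrich_qmax)
                enrichment_frame(results).to_csv(
                    out / "enrichment.tsv", sep="\t", index=False)
                n_sel = sum(r.selected for r in results)
                summary.append(
                    f"enrichment: {n_sel} of {len(results)} terms selected")

        stage = "proximity"
        if "proximity" in config.stages:
            if net_lcc is None:
                net = read_edge_list(config.network_path,
                                     score_column=config.score_column,
                                     min_score=config.min_score)
                net_lcc = largest_connected_component(net)
            if targets is None:
                targets = read_targets_table(config.targets_path)
            if config.keyset_path:
                key = GeneSet.from_file(config.keyset_path, name="G_K",
                                        provenance="G_K")
            else:
                key = gene_sets.get("G_K")
            if key is None or not len(key):
                raise ValueError("proximity stage requires a nonempty key set")
            rows = proximity_table(net_lcc, targets, key,
                                   within_set=config.within_set)
            write_proximity_table(rows, out / "proximity.tsv")
            n_int = sum(r.interferes for r in rows)
            summary.append(
                f"proximity: {n_int} of {len(rows)} ingredients interfere "
                "(S_P < 0)"
            )
    except Exception as exc:  # noqa: BLE001 — annotate and re-raise
        (out / "PARTIAL").write_text(f"failed at stage: {stage}\n{exc}\n")
        raise StageError(stage, exc) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "summary.txt").write_text("".join(f"{s}\n" for s in summary))
    for line in summary:
        logger.info("%s", line)
    return out
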
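"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: a scale-free PPI
background (preferential attachment), two-phenotype log2 expression
matrices with planted differentially expressed genes and planted correlated
gene modules, exponential survival times whose hazard tracks one gene's
expression, and ingredient target sets planted at a controlled graph
distance from a key gene set.  One global seed fans out to fixed
per-component child seeds, so regenerating one input never perturbs the
others; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .genesets import GeneSet
from .graph_core import PPINetwork
from .survival import SurvivalRecord

_SEED_OFFSETS = {"graph": 1, "expression": 2, "survival": 3, "targets": 4}


def _child_seed(seed: int, component: str) -> int:
    return (int(seed) * 1_000_003 + _SEED_OFFSETS[component] * 7919) % (2**31)


@dataclass
class SynthConfig:
    """All generator knobs, chosen to emulate the study conditions.

    Graph: 2,000 nodes with attachment 2 is a desk-scale stand-in for a
    genome-wide interactome (same heavy-tailed degree law, ~10x smaller).
    Expression: 2,000 genes, 40 samples per phenotype, 50 planted DE genes
    shifted by 2 log2 units over N(8, 1) baselines; two planted 60-gene
    modules with within-block correlation 0.8, the first linked to the
    phenotype.  Survival: exponential events, hazard ratio 3 per SD of the
    prognostic gene, 30% censoring.  Targets: 20 ingredients of 10 targets
    each, half planted within 1 hop of a 10-gene key set whose members
    share a 40-node anchor of direct interactors (a protein-complex-like
    neighbourhood; see gen_disease_network).
    """

    seed: int = 1
    # graph
    n_nodes: int = 2000
    attach_m: int = 2
    # expression
    n_genes: int = 2000
    n_samples_per_group: int = 40
    n_planted_de: int = 50
    effect_size_log2fc: float = 2.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    # modules
    n_modules: int = 2
    module_size: int = 60
    within_corr: float = 0.8
    trait_effect: float = 2.0  # latent-mean shift of module1 in disease
    # survival
    hazard_ratio: float = 3.0
    censor_rate: float = 0.3
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    # ingredient targets / key-set context
    n_ingredients: int = 20
    targets_per_ingredient: int = 10
    planted_fraction: float = 0.5
    planting_radius_hops: int = 1
    n_key_genes: int = 10
    anchor_size: int = 40

    def __post_init__(self) -> None:
        for name in ("n_nodes", "attach_m", "n_genes", "n_samples_per_group",
                     "n_ingredients", "targets_per_ingredient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("within_corr", "planted_fraction", "censor_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def gen_ppi(config: SynthConfig) -> PPINetwork:
    """Connected preferential-attachment graph with heavy-tailed degrees.

    Construction: start from a complete graph on m+1 nodes; each new node
    attaches to m distinct existing nodes drawn proportionally to degree.
    Edge count is therefore C(m+1, 2) + m * (n - m - 1).
    """
    n, m = config.n_nodes, config.attach_m
    if n < m + 1:
        raise ValueError("n_nodes must be at least attach_m + 1")
    rng = np.random.default_rng(_child_seed(config.seed, "graph"))
    g = nx.Graph()
    nodes = [_gene_id(i) for i in range(n)]
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            g.add_edge(nodes[i], nodes[j])
    # repeated-nodes list: each edge endpoint appears once per incident edge
    repeated: list[int] = []
    for i in range(m + 1):
        repeated.extend([i] * m)
    for new in range(m + 1, n):
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(int(repeated[rng.integers(0, len(repeated))]))
        for tgt in sorted(chosen):
            g.add_edge(nodes[new], nodes[tgt])
            repeated.extend([new, tgt])
    return PPINetwork(g)


def gen_disease_network(config: SynthConfig) -> tuple[PPINetwork, GeneSet]:
    """Background network plus a key gene set with a shared interactor anchor.

    Starts from the plain preferential-attachment background, designates the
    ``n_key_genes`` last-added (peripheral) nodes as the key disease set,
    and wires every key gene to a common pool of ``anchor_size`` randomly
    chosen interactor nodes.  This emulates a disease protein complex: the
    key genes share direct binding partners, so the anchor nodes are one
    hop from every key gene while remaining mutually non-adjacent.  That is
    the geometry under which a separation score can actually go negative —
    an ingredient whose targets sit in the shared-interactor neighbourhood
    is closer to the whole key set than the key genes (or its own targets)
    are to each other.  Without such structure, planted target sets in a
    homogeneous small-world graph score S >= 0 regardless of proximity.
    """
    net = gen_ppi(config)
    rng = np.random.default_rng(_child_seed(config.seed, "graph") + 101)
    nodes = sorted(net.nodes)
    if config.n_key_genes + config.anchor_size > len(nodes):
        raise ValueError("n_key_genes + anchor_size exceeds n_nodes")
    key_nodes = nodes[-config.n_key_genes:]
    candidates = nodes[: -config.n_key_genes]
    pool_idx = rng.choice(len(candidates), config.anchor_size, replace=False)
    for b in key_nodes:
        for i in pool_idx:
            net.graph.add_edge(b, candidates[i])
    key = GeneSet.from_symbols("G_K", key_nodes, provenance="G_K")
    return net, key


def gen_expression(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, dict[str, pd.DataFrame]]:
    """Two-phenotype log2 expression with planted DE genes and modules.

    Layout: genes 0 .. n_modules*module_size-1 belong to planted modules
    (module1 is phenotype-linked via a latent-factor mean shift of
    ``trait_effect`` in the disease group); the next ``n_planted_de`` genes
    carry a mean shift of ``effect_size_log2fc`` in the disease group; the
    rest are null.  Returns the matrix plus truth tables ``de_genes``,
    ``module_membership`` and ``module_trait``.
    """
    rng = np.random.default_rng(_child_seed(config.seed, "expression"))
    n_gene, nspg = config.n_genes, config.n_samples_per_group
    n_module_genes = config.n_modules * config.module_size
    if n_module_genes + config.n_planted_de > n_gene:
        raise ValueError("planted modules + DE genes exceed n_genes")
    n_samples = 2 * nspg
    samples = [f"S{i:03d}" for i in range(n_samples)]
    phenotype = pd.Series(
        ["normal"] * nspg + ["disease"] * nspg, index=samples, name="phenotype"
    )
    disease_mask = (phenotype == "disease").to_numpy()

    x = config.baseline_mean + config.noise_sd * rng.standard_normal(
        (n_gene, n_samples)
    )

    # planted modules: shared latent factor per module
    module_rows = []
    c = config.within_corr
    for mi in range(config.n_modules):
        latent = rng.standard_normal(n_samples)
        if mi == 0 and config.trait_effect != 0:
            latent = latent + config.trait_effect * disease_mask
        start = mi * config.module_size
        for gi in range(start, start + config.module_size):
            eps = rng.standard_normal(n_samples)
            profile = np.sqrt(c) * latent + np.sqrt(1 - c) * eps
            x[gi] = config.baseline_mean + config.noise_sd * profile
            module_rows.append(
                {"gene": _gene_id(gi), "module": f"planted{mi + 1}",
                 "trait_linked": mi == 0 and config.trait_effect != 0}
            )

    # planted DE genes
    de_rows = []
    if config.effect_size_log2fc != 0:
        for gi in range(n_module_genes, n_module_genes + config.n_planted_de):
            x[gi, disease_mask] += config.effect_size_log2fc
            de_rows.append(
                {"gene": _gene_id(gi), "log2fc": config.effect_size_log2fc}
            )

    values = pd.DataFrame(
        x, index=[_gene_id(i) for i in range(n_gene)], columns=samples
    )
    truth = {
        "de_genes": pd.DataFrame(de_rows, columns=["gene", "log2fc"]),
        "module_membership": pd.DataFrame(
            module_rows, columns=["gene", "module", "trait_linked"]
        ),
        "module_trait": pd.DataFrame(
            [{"module": "planted1",
              "trait_linked": config.trait_effect != 0 and config.n_modules > 0}]
            if config.n_modules > 0 else [],
            columns=["module", "trait_linked"],
        ),
    }
    return ExpressionMatrix(values, phenotype), truth


def gen_coexpression(
    config: SynthConfig, cluster_corr: float = 0.9
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression with power-law-sized correlated gene clusters.

    Emulates the global coexpression structure of real transcriptomes — a
    few large and many small correlated gene groups — so that the
    soft-threshold connectivity distribution is heavy-tailed and a
    scale-free topology fit is meaningful.  Cluster sizes follow the degree
    sequence of a preferential-attachment graph (power-law tail); every
    gene shares its cluster's latent factor with correlation
    ``cluster_corr``.  Returns the matrix and a gene→cluster truth table.
    """
    seed = _child_seed(config.seed, "expression") + 29
    rng = np.random.default_rng(seed)
    n_gene, nspg = config.n_genes, config.n_samples_per_group
    n_samples = 2 * nspg
    # degree sequence of a BA graph sums to ~n_gene when n_ba = n_gene/4
    ba = nx.barabasi_albert_graph(max(10, n_gene // 4), 2,
                                  seed=seed % (2**31))
    sizes = sorted((d for _, d in ba.degree()), reverse=True)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    phenotype = pd.Series(
        ["normal"] * nspg + ["disease"] * nspg, index=samples, name="phenotype"
    )
    c = cluster_corr
    x = np.empty((n_gene, n_samples))
    rows = []
    gi = 0
    for ci, size in enumerate(sizes):
        if gi >= n_gene:
            break
        latent = rng.standard_normal(n_samples)
        for _ in range(min(size, n_gene - gi)):
            eps = rng.standard_normal(n_samples)
            x[gi] = config.baseline_mean + config.noise_sd * (
                np.sqrt(c) * latent + np.sqrt(1 - c) * eps
            )
            rows.append({"gene": _gene_id(gi), "cluster": f"cluster{ci + 1}"})
            gi += 1
    while gi < n_gene:  # degree sum fell short: fill with singleton noise
        x[gi] = config.baseline_mean + config.noise_sd * rng.standard_normal(
            n_samples
        )
        rows.append({"gene": _gene_id(gi), "cluster": "noise"})
        gi += 1
    values = pd.DataFrame(
        x, index=[_gene_id(i) for i in range(n_gene)], columns=samples
    )
    return (
        ExpressionMatrix(values, phenotype),
        pd.DataFrame(rows, columns=["gene", "cluster"]),
    )


def gen_survival(
    config: SynthConfig,
    expression: pd.Series,
) -> list[SurvivalRecord]:
    """Exponential survival records with expression-dependent hazard.

    Each subject's event rate is baseline_hazard * HR^z, z the standardized
    expression of the prognostic gene.  Censoring times are independent
    exponentials with rate tuned so roughly ``censor_rate`` of subjects are
    censored; censor_rate 0 means every event is observed.
    """
    rng = np.random.default_rng(_child_seed(config.seed, "survival"))
    z = expression.to_numpy(dtype=float)
    sd = z.std()
    z = (z - z.mean()) / (sd if sd > 0 else 1.0)
    rate = config.baseline_hazard * config.hazard_ratio**z
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        c_rate = (
            config.censor_rate / (1 - config.censor_rate) * config.baseline_hazard
        )
        t_censor = rng.exponential(1.0 / c_rate, size=len(z))
        observed = t_event <= t_censor
        time = np.minimum(t_event, t_censor)
    else:
        observed = np.ones(len(z), dtype=bool)
        time = t_event
    return [
        SurvivalRecord(str(s), float(t), int(e), float(v))
        for s, t, e, v in zip(expression.index, time, observed, expression)
    ]


def gen_targets(
    config: SynthConfig, net: PPINetwork, key_set: GeneSet
) -> tuple[dict[str, GeneSet], pd.DataFrame]:
    """Ingredient target sets with planted proximity ground truth.

    "Active" ingredients draw targets uniformly from nodes within
    ``planting_radius_hops`` of the key set; "inactive" ones draw uniformly
    from the whole network.  Returns the target map and a truth table with
    an ``active`` flag per ingredient.
    """
    rng = np.random.default_rng(_child_seed(config.seed, "targets"))
    key_nodes = sorted(key_set.members & net.nodes)
    if not key_nodes:
        raise ValueError("key set maps to zero network nodes")
    radius = config.planting_radius_hops
    neighborhood: set[str] = set(key_nodes)
    frontier = set(key_nodes)
    for _ in range(radius):
        nxt: set[str] = set()
        for u in frontier:
            nxt.update(net.graph.neighbors(u))
        neighborhood |= nxt
        frontier = nxt
    pool_active = sorted(neighborhood)
    pool_all = sorted(net.nodes)
    k = config.targets_per_ingredient
    if k > len(pool_active):
        raise ValueError("targets_per_ingredient exceeds neighborhood size")

    n_active = int(round(config.planted_fraction * config.n_ingredients))
    targets: dict[str, GeneSet] = {}
    truth_rows = []
    for i in range(config.n_ingredients):
        ing = f"MOL{i + 1:02d}"
        active = i < n_active
        pool = pool_active if active else pool_all
        chosen = rng.choice(len(pool), size=k, replace=False)
        targets[ing] = GeneSet.from_symbols(ing, [pool[j] for j in chosen])
        truth_rows.append({"ingredient": ing, "active": active})
    return targets, pd.DataFrame(truth_rows, columns=["ingredient", "active"])


def gen_gmt(
    config: SynthConfig, truth: dict[str, pd.DataFrame], n_random_terms: int = 5
) -> dict[str, tuple[str, frozenset[str]]]:
    """A GMT collection with planted-truth terms plus random decoys."""
    rng = np.random.default_rng(_child_seed(config.seed, "targets") + 17)
    collection: dict[str, tuple[str, frozenset[str]]] = {}
    de = truth["de_genes"]
    if len(de):
        collection["PLANTED_DE"] = (
            "planted differentially expressed genes",
            frozenset(de["gene"]),
        )
    mm = truth["module_membership"]
    for module, sub in mm.groupby("module"):
        collection[f"PLANTED_{module.upper()}"] = (
            f"planted coexpression {module}",
            frozenset(sub["gene"]),
        )
    all_genes = [_gene_id(i) for i in range(config.n_genes)]
    for t in range(n_random_terms):
        size = int(rng.integers(20, 60))
        members = rng.choice(len(all_genes), size=size, replace=False)
        collection[f"RANDOM{t + 1}"] = (
            "random decoy term",
            frozenset(all_genes[j] for j in members),
        )
    return collection


def write_all(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``out_dir``; returns the paths.

    Emits network, expression, phenotype, clinical, targets and key-set
    files in the same TSV dialects the readers consume, plus a GMT and the
    truth tables, and a config.json echo of the generating parameters.
    """
    from .enrichment import write_gmt
    from .graph_core import write_edge_list

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    net, key_set = gen_disease_network(config)
    paths["network"] = out / "network.tsv"
    write_edge_list(net, paths["network"])

    mat, truth = gen_expression(config)
    paths["expression"] = out / "expression.tsv"
    mat.values.round(6).to_csv(paths["expression"], sep="\t")
    paths["phenotype"] = out / "phenotype.tsv"
    mat.phenotype.rename("label").to_csv(paths["phenotype"], sep="\t")

    prognostic = (
        truth["de_genes"]["gene"].iloc[0]
        if len(truth["de_genes"])
        else mat.values.index[0]
    )
    records = gen_survival(config, mat.values.loc[prognostic])
    paths["clinical"] = out / "clinical.tsv"
    pd.DataFrame(
        [{"sample": r.sample_id, "time": round(r.time, 6), "event": r.event}
         for r in records]
    ).to_csv(paths["clinical"], sep="\t", index=False)

    paths["keyset"] = out / "keyset.txt"
    key_set.to_file(paths["keyset"])

    targets, target_truth = gen_targets(config, net, key_set)
    paths["targets"] = out / "targets.tsv"
    pd.DataFrame(
        [
            {"ingredient_id": ing, "target_symbol": t}
            for ing in sorted(targets)
            for t in sorted(targets[ing].members)
        ]
    ).to_csv(paths["targets"], sep="\t", index=False)

    paths["gmt"] = out / "collection.gmt"
    write_gmt(gen_gmt(config, truth), paths["gmt"])

    for name, df in truth.items():
        p = out / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    paths["truth_targets"] = out / "truth_targets.tsv"
    target_truth.to_csv(paths["truth_targets"], sep="\t", index=False)

    paths["config"] = out / "config.json"
    paths["config"].write_text(json.dumps(asdict(config), indent=2, sort_keys=True))
    return paths
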
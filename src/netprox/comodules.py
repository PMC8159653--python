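"""Coexpression module detection via topological overlap and tree cutting.

A soft-thresholded adjacency a_ij = |cor(x_i, x_j)|^beta is smoothed into a
topological overlap matrix

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),  TOM_ii = 1,

then genes are clustered by average-linkage on the dissimilarity 1 - TOM and
the tree is cut at a fixed height (default 0.25).  Clusters smaller than the
minimum module size (default 50) are relabelled "grey" (unassigned).  This
is a deliberately static simplification of the dynamic hybrid tree cut used
by full WGCNA; the cut height and minimum size are honoured as stated
parameters.  Module-trait association uses the module eigengene — the first
principal component of the module's standardized expression submatrix —
correlated against the binary phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diffexpr import ExpressionMatrix
from .genesets import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class ModuleConfig:
    """Parameters of the module-detection stage.

    beta: soft-threshold power applied to |correlation|.
    min_module_size: clusters below this size become grey (default 50).
    cut_height: module-merge height — modules whose eigengene dissimilarity
        (1 - correlation) falls below this are merged (default 0.25, i.e.
        eigengene correlation above 0.75).
    branch_cut: static dendrogram height separating coexpression branches
        from the unclustered background (default 0.97; on 1 - TOM, genuine
        modules join far below this while uncorrelated genes join near 1).
    rsq_target: scale-free topology fit R^2 required of a candidate beta.
    """

    beta: int = 6
    min_module_size: int = 50
    cut_height: float = 0.25
    branch_cut: float = 0.97
    rsq_target: float = 0.85

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.cut_height < 1:
            raise ValueError("cut_height must be in (0, 1)")
        if not 0 < self.branch_cut <= 1:
            raise ValueError("branch_cut must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class ModuleAssignment:
    """Gene→module labels plus per-module eigengenes and trait correlations."""

    labels: pd.Series  # index = genes, values = "module1", ..., "grey"
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)
    trait_correlation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def modules(self) -> dict[str, GeneSet]:
        out: dict[str, GeneSet] = {}
        for label in sorted(self.labels.unique()):
            if label == "grey":
                continue
            out[label] = GeneSet.from_symbols(
                label, self.labels.index[self.labels == label]
            )
        return out


def adjacency_matrix(mat: ExpressionMatrix, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |pearson cor|^beta, zero diagonal."""
    x = mat.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).all():
        raise ValueError("expression matrix is constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=mat.values.index, columns=mat.values.index)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit: R^2 and slope of log10 p(k) on log10 k.

    Connectivity k_i = sum_j a_ij is binned into ``n_bins`` equal-width bins;
    the regression runs over bins with nonzero frequency (needs >= 5).
    """
    k = adjacency.to_numpy().sum(axis=1)
    k = k[k > 0]
    if k.size < 10:
        raise ValueError("too few connected genes for a scale-free fit")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    centers, freqs = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        centers.append(k[sel].mean())
        freqs.append(sel.mean())
    if len(centers) < 5:
        raise ValueError("fewer than 5 occupied degree bins")
    lx, ly = np.log10(centers), np.log10(freqs)
    res = stats.linregress(lx, ly)
    return float(res.rvalue**2), float(res.slope)


def select_soft_threshold(
    mat: ExpressionMatrix,
    candidates: list[int] = (1, 2, 3, 4, 5, 6, 8, 10, 12),
    rsq_target: float = 0.85,
) -> int:
    """Smallest candidate power whose scale-free fit R^2 (negative slope)
    reaches ``rsq_target``; falls back to the argmax-R^2 candidate with a
    warning when none qualifies."""
    candidates = sorted(set(int(c) for c in candidates))
    if len(candidates) < 3 and rsq_target > 0:
        logger.warning("fewer than 3 candidate powers supplied")
    fits: dict[int, float] = {}
    for beta in candidates:
        adj = adjacency_matrix(mat, beta)
        try:
            rsq, slope = scale_free_fit(adj)
        except ValueError:
            continue
        score = rsq if slope < 0 else 0.0
        fits[beta] = score
        if score >= rsq_target:
            return beta
    if not fits:
        raise ValueError("scale-free fit failed for every candidate power")
    best = max(fits, key=lambda b: (fits[b], -b))
    logger.warning(
        "no candidate power reached R^2 >= %.2f; returning argmax beta=%d "
        "(R^2=%.3f)", rsq_target, best, fits[best],
    )
    return best


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix from a soft-threshold adjacency.

    Requires a symmetric matrix with zero diagonal and entries in [0, 1].
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.diag(a).any():
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu * a_uj
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    config: ModuleConfig,
    mat: ExpressionMatrix | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM into coexpression modules.

    Branches of the dendrogram below ``branch_cut`` become candidate
    clusters; clusters below ``min_module_size`` are relabelled grey.  When
    an expression matrix is supplied, modules whose eigengenes are nearly
    collinear (dissimilarity 1 - cor below ``cut_height``) are merged, the
    standard treatment of a module split across adjacent branches.
    Surviving modules are labelled module1, module2, ... by decreasing size
    (ties by smallest member symbol).
    """
    t = tom.to_numpy(dtype=float)
    if t.shape[0] != t.shape[1] or not np.allclose(t, t.T, atol=1e-10):
        raise ValueError("TOM must be square and symmetric")
    dissim = 1.0 - t
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip(dissim, 0.0, None)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=config.branch_cut, criterion="distance")

    genes = list(tom.index)
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    kept = [
        members for members in clusters.values()
        if len(members) >= config.min_module_size
    ]
    if mat is not None and len(kept) > 1:
        kept = _merge_collinear(kept, mat, config.cut_height)
    kept.sort(key=lambda m: (-len(m), min(m)))
    labels = pd.Series("grey", index=tom.index, dtype=object)
    for i, members in enumerate(kept, start=1):
        labels.loc[members] = f"module{i}"
    if not kept:
        logger.warning("all genes unassigned (grey): no cluster reached "
                       "min_module_size=%d", config.min_module_size)
    return ModuleAssignment(labels=labels)


def _merge_collinear(
    clusters: list[list[str]], mat: ExpressionMatrix, cut_height: float
) -> list[list[str]]:
    """Greedily merge cluster pairs with eigengene dissimilarity < cut_height."""
    clusters = [list(c) for c in clusters]
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        eigs = [
            module_eigengene(mat, GeneSet.from_symbols("m", c)).to_numpy()
            for c in clusters
        ]
        best: tuple[float, int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = 1.0 - float(np.corrcoef(eigs[i], eigs[j])[0, 1])
                if d < cut_height and (best is None or d < best[0]):
                    best = (d, i, j)
        if best is not None:
            _, i, j = best
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]
            merged = True
    return clusters


# Familiar color aliases for size-ranked module labels (WGCNA convention).
MODULE_COLOR_ALIASES = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple",
)


def color_alias_table(assign: ModuleAssignment) -> pd.DataFrame:
    rows = []
    labels = [l for l in sorted(assign.labels.unique()) if l != "grey"]
    labels.sort(key=lambda l: int(l.replace("module", "")))
    for i, label in enumerate(labels):
        alias = MODULE_COLOR_ALIASES[i] if i < len(MODULE_COLOR_ALIASES) else label
        rows.append({"module": label, "color_alias": alias})
    return pd.DataFrame(rows, columns=["module", "color_alias"])


def module_eigengene(mat: ExpressionMatrix, genes: GeneSet) -> pd.Series:
    """First principal component across samples of the module submatrix.

    Gene profiles are standardized first; the eigengene has unit norm and
    its sign is fixed so it correlates positively with the module's mean
    expression profile.
    """
    members = sorted(genes.members & set(mat.values.index))
    if len(members) < 2:
        raise ValueError("module must contain >= 2 genes present in the matrix")
    x = mat.values.loc[members].to_numpy(dtype=float)
    mu, sd = x.mean(axis=1, keepdims=True), x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    # first right-singular vector = first PC over samples
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    eig = vt[0]
    mean_profile = xs.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=mat.values.columns, name="eigengene")


def module_trait_correlation(
    assign: ModuleAssignment, mat: ExpressionMatrix
) -> pd.DataFrame:
    """Pearson r (and its t-transform p) of each module eigengene with the
    0/1 phenotype (disease = 1).  Fills ``assign.eigengenes`` and
    ``assign.trait_correlation`` and returns the latter."""
    trait = (mat.phenotype == "disease").astype(float).to_numpy()
    rows, eigs = [], {}
    for label, genes in assign.modules().items():
        eig = module_eigengene(mat, genes)
        r, p = stats.pearsonr(eig.to_numpy(), trait)
        rows.append({"module": label, "size": len(genes), "r": float(r),
                     "p": float(p)})
        eigs[label] = eig
    out = pd.DataFrame(rows, columns=["module", "size", "r", "p"])
    assign.eigengenes = pd.DataFrame(eigs)
    assign.trait_correlation = out
    return out


def assemble_gw(
    pos1: GeneSet, pos2: GeneSet, neg1: GeneSet, neg2: GeneSet
) -> GeneSet:
    """G_W = (pos1 ∩ pos2) ∪ (neg1 ∩ neg2): the union of the two cohorts'
    common positively- and negatively-trait-correlated module genes."""
    pos = pos1.intersect(pos2)
    neg = neg1.intersect(neg2)
    return GeneSet("G_W", pos.members | neg.members, provenance="G_W")
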
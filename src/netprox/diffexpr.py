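"""Two-group differential expression with the |log2FC| > 1, BH q < 0.05 contract.

A Welch two-sample t test per gene stands in for a moderated-t fit: no
empirical-Bayes variance shrinkage is applied, because what the pipeline
consumes downstream is only the threshold contract (fold change and
BH-adjusted p), not the exact test statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet
from .graph_core import normalize_symbol

logger = logging.getLogger(__name__)

LFC_THRESHOLD = 1.0
ALPHA = 0.05


@dataclass
class ExpressionMatrix:
    """Genes × samples expression on log2 scale, with a binary phenotype.

    ``values`` rows are genes (index = symbols), columns are sample ids;
    ``phenotype`` maps each sample id to ``"normal"`` or ``"disease"``.
    """

    values: pd.DataFrame
    phenotype: pd.Series  # index = sample ids, values in {"normal", "disease"}

    def __post_init__(self) -> None:
        self.values.index = [normalize_symbol(g) for g in self.values.index]
        self.phenotype = self.phenotype.reindex(self.values.columns)
        labels = set(self.phenotype.unique())
        if not labels <= {"normal", "disease"}:
            raise ValueError(f"phenotype labels must be normal/disease, got {labels}")
        for lab in ("normal", "disease"):
            if (self.phenotype == lab).sum() < 2:
                raise ValueError(f"need >=2 samples with phenotype {lab!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if float(np.nanmax(self.values.to_numpy())) > 50:
            logger.warning(
                "expression values exceed 50 — input looks like unlogged counts; "
                "the matrix is assumed to be log2-scale"
            )

    @classmethod
    def from_tsv(cls, expr_path: str | Path, phen_path: str | Path
                 ) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        phen = pd.read_csv(phen_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(values, phen)

    def samples(self, label: str) -> list[str]:
        return list(self.phenotype.index[self.phenotype == label])


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving with input."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_group_test(
    mat: ExpressionMatrix,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-gene Welch t, BH adjustment and up/down/none direction calls.

    Returns a DataFrame indexed by gene with columns ``log2FC`` (disease
    minus normal mean), ``p_raw``, ``p_adj``, ``direction`` and
    ``zero_variance``.  Genes with zero variance in both groups get p = 1
    and are flagged.
    """
    dis = mat.values[mat.samples("disease")].to_numpy(dtype=float)
    nor = mat.values[mat.samples("normal")].to_numpy(dtype=float)
    log2fc = dis.mean(axis=1) - nor.mean(axis=1)

    zero_var = (dis.var(axis=1) == 0) & (nor.var(axis=1) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(dis, nor, axis=1, equal_var=False)
    p = np.where(zero_var, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)  # equal-mean zero-variance edge cases
    p_adj = bh_adjust(p)

    direction = np.full(len(log2fc), "none", dtype=object)
    sig = p_adj < alpha
    direction[(log2fc > lfc_threshold) & sig] = "up"
    direction[(log2fc < -lfc_threshold) & sig] = "down"

    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_raw": p,
            "p_adj": p_adj,
            "direction": direction,
            "zero_variance": zero_var,
        },
        index=mat.values.index,
    )


def deg_sets(deg_table: pd.DataFrame) -> tuple[GeneSet, GeneSet]:
    """(up, down) gene sets from a DEG table."""
    up = deg_table.index[deg_table["direction"] == "up"]
    down = deg_table.index[deg_table["direction"] == "down"]
    return (
        GeneSet.from_symbols("up", up),
        GeneSet.from_symbols("down", down),
    )


def intersect_deg_sets(set1: GeneSet, set2: GeneSet) -> GeneSet:
    """Intersection of two cohorts' DEG sets (the G_D assembly)."""
    out = set1.intersect(set2, name="G_D", provenance="G_D")
    if not out.members:
        logger.info("DEG intersection is empty")
    return out
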
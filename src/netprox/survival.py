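"""Expression-stratified Kaplan–Meier estimation and log-rank screening.

Each candidate gene's cohort is split at the median expression value (ties
to the low group), the two strata are compared with the standard two-group
log-rank test, and genes with p < 0.05 are called survival-related.  No
multiple-testing correction is applied by default, mirroring the plain
per-gene screen convention; BH adjustment is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .diffexpr import ExpressionMatrix, bh_adjust
from .genesets import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class SurvivalRecord:
    """One subject: follow-up time (days), event flag, optional expression."""

    sample_id: str
    time: float
    event: int  # 1 = death observed, 0 = censored
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.sample_id}: negative time {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0/1")


def read_clinical_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a clinical TSV with columns sample, time, event."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns)
    return [
        SurvivalRecord(str(r[cols[0]]), float(r[cols[1]]), int(r[cols[2]]))
        for _, r in df.iterrows()
    ]


def median_split(values: pd.Series) -> pd.Series:
    """Label samples ``high`` (value > median) or ``low`` (value <= median).

    Requires >= 4 samples; an all-identical vector cannot be split.
    """
    if len(values) < 4:
        raise ValueError("median split needs >= 4 samples")
    if values.nunique() == 1:
        raise ValueError("degenerate split: all expression values identical")
    med = values.median()
    labels = pd.Series(
        np.where(values > med, "high", "low"), index=values.index
    )
    if (labels == "high").sum() == 0:
        raise ValueError("degenerate split: no sample above the median")
    return labels


def km_curve(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate as a right-continuous step table.

    Returns a DataFrame with columns ``time`` and ``survival``; S(0) = 1.
    """
    if not records:
        raise ValueError("no survival records")
    times = [r.time for r in records]
    events = [r.event for r in records]
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    out = sf.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, p from chi2_1)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if not any(r.event for r in [*group_a, *group_b]):
        raise ValueError("no events observed in either group")
    res = _ll_logrank(
        [r.time for r in group_a],
        [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


def survival_screen(
    genes: GeneSet,
    expr: ExpressionMatrix,
    clin: Sequence[SurvivalRecord],
    alpha: float = 0.05,
    adjust: str | None = None,
) -> tuple[GeneSet, pd.DataFrame]:
    """Median-split log-rank screen over a gene set.

    Returns the survival-related gene set (p < alpha, or adjusted p when
    ``adjust='bh'``) and the per-gene statistic table.  Samples present in
    both the expression matrix and the clinical table are used.
    """
    clin_by_id = {r.sample_id: r for r in clin}
    shared = [s for s in expr.values.columns if s in clin_by_id]
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared between expression and "
                         "clinical tables")
    rows = []
    for gene in genes:
        if gene not in expr.values.index:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        vals = expr.values.loc[gene, shared]
        try:
            labels = median_split(vals)
        except ValueError:
            logger.warning("gene %s: degenerate expression split; skipped", gene)
            continue
        high = [clin_by_id[s] for s in shared if labels[s] == "high"]
        low = [clin_by_id[s] for s in shared if labels[s] == "low"]
        stat, p = logrank_test(high, low)
        rows.append({"gene": gene, "chi2": stat, "p": p})
    table = pd.DataFrame(rows, columns=["gene", "chi2", "p"])
    if len(table):
        if adjust == "bh":
            table["p_adj"] = bh_adjust(table["p"])
            passing = table.loc[table["p_adj"] < alpha, "gene"]
        else:
            passing = table.loc[table["p"] < alpha, "gene"]
    else:
        passing = []
    return GeneSet.from_symbols("survival_related", passing), table
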
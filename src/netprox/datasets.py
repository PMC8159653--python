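"""Packaged reference tables for the herbal-formula case study.

Three small TSV fixtures ship with the package, transcribed from the
published study of Yinchenhao decoction (YCHD) against hepatocellular
carcinoma:

* ``admet_ingredients.tsv`` — ADMET assessment of the 36 blood-absorbed
  small molecules (GI absorption class, predicted oral bioavailability %).
* ``predicted_targets.tsv`` — the 105 predicted protein targets of the
  formula's ingredients (symbol, protein name, UniProt accession).
* ``reported_proximity.tsv`` — the 17 published per-ingredient set-distance
  rows (d_S, d_C, d_K, S_P) on the study's genome-wide background network.

The proximity rows are *reference output*, not recomputation targets: the
background interactome behind them (16,677 proteins, 243,603 interactions
merged from 15 databases) is not recoverable from the publication.  Each
loader validates the structural invariants the pipeline relies on.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genesets import GeneSet
from .screening import IngredientRecord, read_admet_table


def _data_path(name: str):
    return resources.files("netprox").joinpath("data", name)


def load_admet_table() -> list[IngredientRecord]:
    """The 36-ingredient ADMET table; validates row count and ranges."""
    with resources.as_file(_data_path("admet_ingredients.tsv")) as p:
        records = read_admet_table(p)
    if len(records) != 36:
        raise ValueError(f"ADMET fixture must have 36 rows, got {len(records)}")
    return records


def load_target_table() -> pd.DataFrame:
    """The 105-target prediction table (symbol, protein name, UniProt)."""
    with resources.as_file(_data_path("predicted_targets.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    if len(df) != 105:
        raise ValueError(f"target fixture must have 105 rows, got {len(df)}")
    if df["symbol"].duplicated().any():
        raise ValueError("duplicate target symbols in fixture")
    return df


def load_target_set() -> GeneSet:
    """The pooled predicted targets as a GeneSet."""
    return GeneSet.from_symbols(
        "predicted_targets", load_target_table()["symbol"], provenance="custom"
    )


def load_reported_proximity() -> pd.DataFrame:
    """The 17 published proximity rows, validated against the distance
    orderings every row must satisfy (d_C <= d_S and d_K > d_S)."""
    with resources.as_file(_data_path("reported_proximity.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    if len(df) != 17:
        raise ValueError(f"proximity fixture must have 17 rows, got {len(df)}")
    if not (df["d_C"] <= df["d_S"]).all():
        raise ValueError("fixture violates d_C <= d_S")
    if not (df["d_K"] > df["d_S"]).all():
        raise ValueError("fixture violates d_K > d_S")
    return df
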
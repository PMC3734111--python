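"""Bundled worked-example tables.

Two small fixtures ship with the package, transcribed from the published
multi-tissue survey they illustrate:

* a signal matrix of 102 transport-gene probe rows over 11 tissues
  (tissue-level values, so each tissue is modeled as a single replicate),
  together with its curated gene list (class and paralog-family labels);
* a fold-change matrix of 25 consensus-candidate genes over the 8
  epithelial tissues, expressed relative to the adult whole organism.

They make every stage of the pipeline runnable and checkable without any
external download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .atlas import (
    AtlasMatrix,
    EnrichmentTable,
    GeneList,
    read_atlas,
    read_gene_list,
)

__all__ = [
    "load_table1_atlas",
    "load_table1_genelist",
    "load_table2_enrichment",
]

_DATA = resources.files("epicore") / "data"


def load_table1_atlas() -> AtlasMatrix:
    """The 102-probe transport-gene signal matrix over 11 tissues."""
    return read_atlas(_DATA / "table1_signals.tsv", _DATA / "table1_samples.tsv")


def load_table1_genelist() -> GeneList:
    """Curated transport-gene classes (V-ATPase subunits, CPA exchangers,
    channels, ...) with V-ATPase paralog families labelled by subunit."""
    return read_gene_list(_DATA / "table1_genelist.tsv")


def load_table2_enrichment() -> EnrichmentTable:
    """The 25-gene epithelial consensus candidate list as fold changes over
    the adult whole organism (floor 1, signal units)."""
    with resources.as_file(_DATA / "table2_foldchange.tsv") as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    tissues = [c for c in df.columns
               if c not in ("probe_id", "gene_symbol", "description")]
    idx = pd.Index(df["probe_id"], name="probe_id")
    fc = pd.DataFrame({t: df[t].astype(float).to_numpy() for t in tissues},
                      index=idx)
    symbols = pd.Series(df["gene_symbol"].to_numpy(), index=idx,
                        name="gene_symbol")
    table = EnrichmentTable(fold_change=fc, gene_symbols=symbols,
                            reference_tissue="whole_fly", floor=1.0)
    table.descriptions = pd.Series(df["description"].to_numpy(), index=idx)
    return table
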
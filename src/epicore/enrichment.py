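"""Replicate aggregation and fold-change enrichment versus a reference tissue.

The enrichment statistic is deliberately simple: the ratio of a probe's mean
tissue signal to its mean signal in a whole-organism reference, with a small
signal floor applied to both operands so that zero signals yield bounded,
positive ratios.  No variance model or p-value is attached — the workflow is
a screening filter, not a hypothesis test.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import AnalysisConfig, AtlasMatrix, EnrichmentTable, TissueProfile

__all__ = [
    "aggregate_replicates",
    "fold_change",
    "max_enrichment",
    "min_enrichment",
]


def aggregate_replicates(
    atlas: AtlasMatrix,
    config: AnalysisConfig | None = None,
    tissues: Sequence[str] | None = None,
) -> TissueProfile:
    """Collapse replicate samples to per-tissue means.

    ``mean_signal`` is the arithmetic mean of the non-missing replicate
    signals; ``present_fraction`` is the fraction of non-missing replicates
    whose detection call is present (NaN when the atlas carries no calls);
    a cell whose replicates are all missing stays missing.
    """
    del config  # only the (fixed) mean rule is defined
    tissue_list = list(tissues) if tissues is not None else atlas.tissues
    mean_cols: dict[str, np.ndarray] = {}
    pf_cols: dict[str, np.ndarray] = {}
    n_cols: dict[str, np.ndarray] = {}
    for t in tissue_list:
        samp = atlas.samples_of(t)  # raises for unknown/empty tissue
        block = atlas.signals[samp]
        n = block.notna().sum(axis=1)
        mean_cols[t] = block.mean(axis=1, skipna=True).to_numpy()
        n_cols[t] = n.to_numpy()
        if atlas.calls is not None:
            cblock = atlas.calls[samp]
            present = (cblock == "P") & block.notna()
            with np.errstate(invalid="ignore"):
                pf_cols[t] = (present.sum(axis=1) / n).to_numpy()
        else:
            pf_cols[t] = np.full(len(block), np.nan)
    idx = atlas.probe_ids
    return TissueProfile(
        mean_signal=pd.DataFrame(mean_cols, index=idx),
        present_fraction=pd.DataFrame(pf_cols, index=idx),
        n_replicates=pd.DataFrame(n_cols, index=idx).astype(int),
        gene_symbols=atlas.gene_symbols.copy(),
    )


def fold_change(profile: TissueProfile, config: AnalysisConfig) -> EnrichmentTable:
    """Fold change of every tissue over the reference tissue.

    ``FC(g, t) = max(mean(g, t), floor) / max(mean(g, ref), floor)``; cells
    missing in either operand are undefined (NaN), and the reference column
    is exactly 1 wherever the reference signal is defined.
    """
    if config.floor <= 0:
        raise ValueError(f"floor must be positive, got {config.floor}")
    ref = config.reference_tissue
    if ref not in profile.tissues:
        raise ValueError(f"reference tissue {ref!r} not in profile")
    num = profile.mean_signal.clip(lower=config.floor)
    den = profile.mean_signal[ref].clip(lower=config.floor)
    fc = num.div(den, axis=0)
    fc = fc.where(profile.mean_signal.notna())          # numerator missing
    fc = fc.where(profile.mean_signal[ref].notna(), axis=0)  # reference missing
    ref_defined = profile.mean_signal[ref].notna()
    fc[ref] = np.where(ref_defined, 1.0, np.nan)
    return EnrichmentTable(
        fold_change=fc,
        gene_symbols=profile.gene_symbols.copy(),
        reference_tissue=ref,
        floor=config.floor,
    )


def _gene_row(enrichment: EnrichmentTable, gene: str,
              tissues: Sequence[str]) -> pd.Series:
    """Fold-change row for a probe id or gene symbol over *tissues*.

    A symbol covered by several probe sets is summarized by the per-tissue
    maximum across its probes.
    """
    unknown = [t for t in tissues if t not in enrichment.fold_change.columns]
    if unknown:
        raise ValueError(f"tissues not in enrichment table: {unknown}")
    if gene in enrichment.fold_change.index:
        return enrichment.fold_change.loc[gene, list(tissues)]
    mask = enrichment.gene_symbols == gene
    if not mask.any():
        raise KeyError(f"gene {gene!r} not in enrichment table")
    return enrichment.fold_change.loc[mask.to_numpy(), list(tissues)].max(axis=0)


def max_enrichment(enrichment: EnrichmentTable, gene: str,
                   tissues: Sequence[str]) -> tuple[str, float]:
    """Largest defined fold change of *gene* over *tissues* and its tissue.

    Ties are broken by the order of *tissues*.
    """
    row = _gene_row(enrichment, gene, tissues)
    if row.isna().all():
        raise ValueError(f"all fold changes undefined for {gene!r}")
    best = row.max()
    for t in tissues:
        if not np.isnan(row[t]) and row[t] == best:
            return t, float(best)
    raise AssertionError("unreachable")


def min_enrichment(enrichment: EnrichmentTable, gene: str,
                   tissues: Sequence[str]) -> tuple[str, float]:
    """Smallest defined fold change of *gene* over *tissues* and its tissue."""
    row = _gene_row(enrichment, gene, tissues)
    if row.isna().all():
        raise ValueError(f"all fold changes undefined for {gene!r}")
    worst = row.min()
    for t in tissues:
        if not np.isnan(row[t]) and row[t] == worst:
            return t, float(worst)
    raise AssertionError("unreachable")
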
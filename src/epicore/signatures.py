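"""Signature detection: consensus core, strict detection calls, top-N
specificity, curated-list profiling and dominant-isoform selection.

Three complementary ways of asking "which genes characterize these
epithelia?":

* ``core_signature`` — the hypothesis-free consensus: genes whose enrichment
  over the whole organism is at least ``tau`` in *every* configured
  epithelium.
* ``strict_call_signature`` — the rejected stricter alternative: present
  detection calls in all inside tissues and absent calls in all outside
  tissues.  On real atlases this tends to return nothing, which is exactly
  why the fold-change consensus exists.
* ``tissue_specific_top_n`` — the per-tissue view: the N genes most enriched
  in a single tissue.

The hypothesis-led route profiles a curated gene list over the atlas
(``profile_gene_list``) and, within a paralog family, picks the single
dominant isoform per tissue (``dominant_isoform``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .atlas import AnalysisConfig, EnrichmentTable, GeneList, TissueProfile

__all__ = [
    "SignatureResult",
    "DominantIsoform",
    "core_signature",
    "criterion_audit",
    "strict_call_signature",
    "tissue_specific_top_n",
    "profile_gene_list",
    "dominant_isoform",
    "family_profiles",
]


@dataclass
class SignatureResult:
    """A detected gene set with per-tissue evidence and audit flags.

    ``table`` is indexed by probe_id and carries ``gene_symbol``, one evidence
    column per tissue, one boolean ``pass__<tissue>`` column per tissue and an
    ``overall_pass`` column; every input gene is retained (pass or fail) so a
    criterion can be audited after the fact.  ``criterion`` snapshots the
    thresholds used.
    """

    mode: str  # consensus_fc | strict_calls | tissue_specific
    table: pd.DataFrame
    criterion: dict
    tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("consensus_fc", "strict_calls", "tissue_specific"):
            raise ValueError(f"unknown signature mode {self.mode!r}")

    @property
    def pass_table(self) -> pd.DataFrame:
        return self.table[self.table["overall_pass"]]

    @property
    def pass_probes(self) -> list[str]:
        return list(self.pass_table.index)

    @property
    def pass_symbols(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.pass_table["gene_symbol"]:
            seen.setdefault(s, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.table)


def _sorted_consensus(table: pd.DataFrame) -> pd.DataFrame:
    key = table.assign(
        _neg=-table["min_evidence"].fillna(-np.inf),
        _sym=table["gene_symbol"],
        _pid=table.index,
    )
    return key.sort_values(["_neg", "_sym", "_pid"]).drop(
        columns=["_neg", "_sym", "_pid"]
    )


def core_signature(enrichment: EnrichmentTable,
                   config: AnalysisConfig) -> SignatureResult:
    """Genes at least ``tau``-fold enriched in every configured epithelium.

    A probe passes iff its fold change is defined and >= tau in each tissue
    of ``config.epithelial_tissues``; a missing cell fails the probe, since
    consistent enrichment cannot be asserted on missing evidence.  Output is
    sorted by descending minimum fold change, ties by gene symbol then
    probe_id, and retains failing genes with their per-tissue flags.
    """
    tissues = list(config.epithelial_tissues)
    if not tissues:
        raise ValueError("epithelial tissue set is empty")
    missing = [t for t in tissues if t not in enrichment.fold_change.columns]
    if missing:
        raise ValueError(f"epithelial tissues not in enrichment table: {missing}")
    ev = enrichment.fold_change[tissues]
    flags = ev.notna() & (ev >= config.tau)
    table = pd.DataFrame(index=enrichment.probe_ids)
    table["gene_symbol"] = enrichment.gene_symbols
    for t in tissues:
        table[t] = ev[t]
    for t in tissues:
        table[f"pass__{t}"] = flags[t]
    table["min_evidence"] = ev.min(axis=1, skipna=True).where(~ev.isna().any(axis=1))
    table["overall_pass"] = flags.all(axis=1)
    table = _sorted_consensus(table)
    criterion = {"tau": config.tau, "tissues": tissues,
                 "reference_tissue": enrichment.reference_tissue,
                 "floor": enrichment.floor}
    return SignatureResult("consensus_fc", table, criterion, tuple(tissues))


def criterion_audit(result: SignatureResult,
                    config: AnalysisConfig | None = None,
                    published: Iterable[str] | None = None) -> pd.DataFrame:
    """Cells of a consensus result that fall below the threshold.

    For every gene of *published* (gene symbols or probe ids; default: all
    genes in the result) each evidence cell that is undefined or below tau is
    listed as a ``(probe_id, gene_symbol, tissue, value)`` row, in result
    order then configured tissue order.  The audit is empty exactly when
    every included gene passes overall.
    """
    if result.mode != "consensus_fc":
        raise ValueError("criterion_audit requires a consensus_fc result")
    tau = config.tau if config is not None else float(result.criterion["tau"])
    table = result.table
    if published is not None:
        wanted = set(published)
        mask = table.index.isin(wanted) | table["gene_symbol"].isin(wanted)
        table = table[mask]
    rows = []
    for pid, row in table.iterrows():
        for t in result.tissues:
            v = row[t]
            if np.isnan(v) or v < tau:
                rows.append((pid, row["gene_symbol"], t, v))
    return pd.DataFrame(rows, columns=["probe_id", "gene_symbol",
                                       "tissue", "value"])


def strict_call_signature(profile: TissueProfile,
                          config: AnalysisConfig,
                          inside: Sequence[str] | None = None,
                          outside: Sequence[str] | None = None,
                          present_min: float = 1.0,
                          absent_max: float = 0.0) -> SignatureResult:
    """Detection-call consensus: present inside, absent outside.

    A gene passes iff its present-fraction is >= *present_min* in every
    *inside* tissue and <= *absent_max* in every *outside* tissue.  With the
    defaults (1.0 / 0.0) this is the "present in all epithelia and absent in
    all other tissues" rule — stringent enough that on realistic atlases it
    returns little or nothing.
    """
    inside = list(inside) if inside is not None else list(config.epithelial_tissues)
    if outside is None:
        outside = [t for t in profile.tissues
                   if t not in inside and t != config.reference_tissue]
    outside = list(outside)
    overlap = set(inside) & set(outside)
    if overlap:
        raise ValueError(f"inside/outside tissue sets overlap: {sorted(overlap)}")
    if not inside:
        raise ValueError("inside tissue set is empty")
    pf = profile.present_fraction
    for t in inside + outside:
        if t not in pf.columns:
            raise ValueError(f"tissue {t!r} not in profile")
    tissues = inside + outside
    table = pd.DataFrame(index=profile.probe_ids)
    table["gene_symbol"] = profile.gene_symbols
    for t in tissues:
        table[t] = pf[t]
    for t in inside:
        table[f"pass__{t}"] = pf[t].notna() & (pf[t] >= present_min)
    for t in outside:
        table[f"pass__{t}"] = pf[t].notna() & (pf[t] <= absent_max)
    flag_cols = [f"pass__{t}" for t in tissues]
    table["min_evidence"] = table[inside].min(axis=1)
    table["overall_pass"] = table[flag_cols].all(axis=1)
    table = _sorted_consensus(table)
    criterion = {"present_min": present_min, "absent_max": absent_max,
                 "inside": inside, "outside": outside}
    return SignatureResult("strict_calls", table, criterion, tuple(tissues))


def tissue_specific_top_n(enrichment: EnrichmentTable, tissue: str,
                          config: AnalysisConfig,
                          merge_with: str | None = None) -> SignatureResult:
    """The ``top_n`` genes most enriched in one tissue.

    Genes are ranked by descending fold change in *tissue*, ties broken by
    gene symbol then probe_id; undefined cells are excluded.  With
    *merge_with* set (the cognate larval/adult partner), the ranking uses the
    per-gene maximum across the two columns — the "in either larvae or
    adult" reading of tissue specificity.
    """
    cols = [tissue] + ([merge_with] if merge_with else [])
    for t in cols:
        if t not in enrichment.fold_change.columns:
            raise ValueError(f"tissue {t!r} not in enrichment table")
    ev = enrichment.fold_change[cols].max(axis=1)
    keep = ev.notna()
    table = pd.DataFrame(index=enrichment.probe_ids[keep])
    table["gene_symbol"] = enrichment.gene_symbols[keep]
    label = tissue if not merge_with else f"{tissue}|{merge_with}"
    table[label] = ev[keep]
    table = table.assign(_neg=-table[label], _sym=table["gene_symbol"],
                         _pid=table.index)
    table = table.sort_values(["_neg", "_sym", "_pid"]).drop(
        columns=["_neg", "_sym", "_pid"])
    table = table.head(config.top_n)
    table[f"pass__{label}"] = True
    table["overall_pass"] = True
    criterion = {"top_n": config.top_n, "tissue": tissue,
                 "merge_with": merge_with,
                 "reference_tissue": enrichment.reference_tissue}
    return SignatureResult("tissue_specific", table, criterion, (label,))


def profile_gene_list(profile: TissueProfile, genes: GeneList,
                      config: AnalysisConfig | None = None,
                      tissues: Sequence[str] | None = None) -> pd.DataFrame:
    """Map a curated gene list onto the atlas, preserving list order.

    Returns one row per list entry (one per matching probe), grouped under
    their class labels, with an ``in_atlas`` flag; entries absent from the
    atlas are flagged, never dropped.  When a symbol occurs k times in the
    list and is covered by k probe sets, occurrences are aligned to probes in
    order; a unique occurrence of a multi-probe symbol expands to all of its
    probes.
    """
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    tissue_list = list(tissues) if tissues is not None else profile.tissues
    by_symbol: dict[str, list[str]] = {}
    for pid, sym in profile.gene_symbols.items():
        by_symbol.setdefault(sym, []).append(pid)
    occurrences = genes.entries.groupby("gene_symbol", sort=False).cumcount()
    counts = genes.entries["gene_symbol"].value_counts()

    rows = []
    for (_, entry), occ in zip(genes.entries.iterrows(), occurrences):
        sym = entry["gene_symbol"]
        probes = by_symbol.get(sym, [])
        if not probes:
            chosen: list[str | None] = [None]
        elif counts[sym] > 1:
            chosen = [probes[occ]] if occ < len(probes) else [None]
        else:
            chosen = list(probes)
        for pid in chosen:
            row = {"class_label": entry["class_label"],
                   "family_label": entry.get("family_label", ""),
                   "gene_symbol": sym,
                   "probe_id": pid if pid is not None else "",
                   "in_atlas": pid is not None}
            for t in tissue_list:
                row[t] = (profile.mean_signal.at[pid, t]
                          if pid is not None else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


class DominantIsoform(NamedTuple):
    gene_symbol: str
    signal: float
    runner_up_ratio: float
    ambiguous: bool


def dominant_isoform(profile: TissueProfile, family: Iterable[str],
                     tissue: str, floor: float = 1.0) -> DominantIsoform:
    """The family member with the highest signal in a tissue.

    Gene-level signal is the per-tissue maximum across a symbol's probes.
    Ties pick the lexicographically smallest symbol and set ``ambiguous``.
    ``runner_up_ratio`` is dominant/(second-highest) with the floor applied
    to both (NaN for a singleton family).
    """
    if tissue not in profile.tissues:
        raise ValueError(f"tissue {tissue!r} not in profile")
    fam = list(dict.fromkeys(family))
    gene_sig = profile.gene_level_signal([tissue])[tissue]
    present = [g for g in fam if g in gene_sig.index]
    if not present:
        raise ValueError("no family member present in the atlas")
    sig = gene_sig.loc[present].astype(float)
    sig = sig.dropna()
    if sig.empty:
        raise ValueError("family signals are all missing in this tissue")
    best = sig.max()
    winners = sorted(sig.index[sig == best])
    dominant = winners[0]
    others = sig.drop(index=dominant)
    if others.empty:
        ratio = float("nan")
    else:
        ratio = max(best, floor) / max(others.max(), floor)
    return DominantIsoform(dominant, float(best), float(ratio),
                           len(winners) > 1)


def family_profiles(profile: TissueProfile, genes: GeneList,
                    tissues: Sequence[str] | None = None,
                    floor: float = 1.0) -> pd.DataFrame:
    """Dominant isoform of every labelled family in every tissue.

    One row per (family_label, tissue) with the dominant symbol, its signal
    and the runner-up ratio; the dominant signal is by construction at least
    every other member's signal in that tissue.
    """
    tissue_list = list(tissues) if tissues is not None else profile.tissues
    families = [f for f in dict.fromkeys(genes.entries["family_label"]) if f]
    rows = []
    for fam in families:
        members = genes.family(fam)
        for t in tissue_list:
            try:
                dom = dominant_isoform(profile, members, t, floor=floor)
            except ValueError:
                continue
            rows.append({"family_label": fam, "tissue": t,
                         "dominant": dom.gene_symbol, "signal": dom.signal,
                         "runner_up_ratio": dom.runner_up_ratio,
                         "ambiguous": dom.ambiguous})
    return pd.DataFrame(rows)
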
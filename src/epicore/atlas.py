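"""Core domain types and tab-separated IO for expression atlases.

An *atlas* is a replicate-level signal matrix (probe sets x samples) with
sample metadata (tissue, life stage, replicate index) and optional Affymetrix
style detection calls (present / marginal / absent).  Downstream stages work
on two derived tables: a :class:`TissueProfile` (per-probe, per-tissue mean
signal and present-fraction) and an :class:`EnrichmentTable` (per-probe,
per-tissue fold change over a whole-organism reference).

Signals are arbitrary non-negative fluorescence units and are never rescaled
on input: every downstream statistic is a ratio or a rank.  Missing cells are
explicit (NaN) and are never silently converted to zero.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIFE_STAGES",
    "DETECTION_CALLS",
    "EPITHELIAL_TISSUES",
    "COGNATE_PAIRS",
    "DEFAULT_REFERENCE",
    "AnalysisConfig",
    "AtlasMatrix",
    "TissueProfile",
    "EnrichmentTable",
    "GeneList",
    "read_atlas",
    "read_gene_list",
    "write_table",
    "read_table",
]

LIFE_STAGES = ("adult", "larval", "whole", "other")
DETECTION_CALLS = ("P", "M", "A")

#: The eight transporting epithelia of the alimentary canal, adult and larval,
#: in the canonical column order used by every report.
EPITHELIAL_TISSUES = (
    "adult_salivary_gland",
    "adult_midgut",
    "adult_tubule",
    "adult_hindgut",
    "larval_salivary_gland",
    "larval_midgut",
    "larval_tubule",
    "larval_hindgut",
)

#: Adult/larval versions of the same organ ("cognate pairs").
COGNATE_PAIRS = (
    ("adult_salivary_gland", "larval_salivary_gland"),
    ("adult_midgut", "larval_midgut"),
    ("adult_tubule", "larval_tubule"),
    ("adult_hindgut", "larval_hindgut"),
)

DEFAULT_REFERENCE = "whole_fly"


@dataclass(frozen=True)
class AnalysisConfig:
    """Named constants of the analysis.

    Parameters
    ----------
    epithelial_tissues :
        Ordered tissue set over which the consensus criterion is evaluated.
    reference_tissue :
        Whole-organism sample used as the enrichment denominator.
    tau :
        Consensus enrichment threshold: a gene must be at least ``tau``-fold
        enriched in *every* epithelial tissue to enter the core signature.
    top_n :
        Number of genes retained in a tissue-specificity ranking.
    floor :
        Signal floor applied to both numerator and denominator of every fold
        change, bounding ratios when signals reach zero.
    aggregation :
        Replicate aggregation rule; only ``"mean"`` is defined.
    rng_seed :
        Seed for any randomized step downstream.
    """

    epithelial_tissues: tuple[str, ...] = EPITHELIAL_TISSUES
    reference_tissue: str = DEFAULT_REFERENCE
    tau: float = 2.5
    top_n: int = 50
    floor: float = 1.0
    aggregation: str = "mean"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")
        if self.floor <= 0:
            raise ValueError(f"floor must be positive, got {self.floor}")
        if self.aggregation != "mean":
            raise ValueError(f"unsupported aggregation {self.aggregation!r}")
        if self.reference_tissue in self.epithelial_tissues:
            raise ValueError("reference_tissue must not be an epithelial tissue")
        if len(set(self.epithelial_tissues)) != len(self.epithelial_tissues):
            raise ValueError("epithelial_tissues contains duplicates")

    def check_tissues(self, available: Iterable[str]) -> None:
        """Raise if the configured tissue set is not contained in *available*."""
        avail = set(available)
        missing = [t for t in self.epithelial_tissues if t not in avail]
        if missing:
            raise ValueError(f"epithelial tissues not in atlas: {missing}")

    def to_dict(self) -> dict:
        return {
            "epithelial_tissues": list(self.epithelial_tissues),
            "reference_tissue": self.reference_tissue,
            "tau": self.tau,
            "top_n": self.top_n,
            "floor": self.floor,
            "aggregation": self.aggregation,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "epithelial_tissues" in d:
            d["epithelial_tissues"] = tuple(d["epithelial_tissues"])
        return cls(**d)

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def _check_signals(signals: pd.DataFrame) -> None:
    if signals.index.has_duplicates:
        dups = signals.index[signals.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe_id: {dups}")
    vals = signals.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative signal values are not allowed")


@dataclass
class AtlasMatrix:
    """Replicate-level signal matrix with sample metadata.

    Attributes
    ----------
    signals : DataFrame
        probe_id x sample_id, float; NaN marks a missing cell.
    gene_symbols : Series
        probe_id -> gene symbol; symbols may repeat across probes.
    samples : DataFrame
        Indexed by sample_id with columns ``tissue``, ``life_stage``,
        ``replicate``.
    calls : DataFrame or None
        Detection calls, same shape as ``signals``, values in {P, M, A}.
    """

    signals: pd.DataFrame
    gene_symbols: pd.Series
    samples: pd.DataFrame
    calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_signals(self.signals)
        if not self.gene_symbols.index.equals(self.signals.index):
            raise ValueError("gene_symbols index must match signals probe ids")
        extra = set(self.signals.columns) ^ set(self.samples.index)
        if extra:
            raise ValueError(f"sample/metadata mismatch for: {sorted(extra)}")
        for col in ("tissue", "life_stage", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        bad_stage = set(self.samples["life_stage"]) - set(LIFE_STAGES)
        if bad_stage:
            raise ValueError(f"unknown life_stage values: {sorted(bad_stage)}")
        if (self.samples["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")
        pairs = self.samples[["tissue", "replicate"]]
        if pairs.duplicated().any():
            raise ValueError("(tissue, replicate) pairs must be unique")
        if self.calls is not None:
            if not self.calls.index.equals(self.signals.index) or list(
                self.calls.columns
            ) != list(self.signals.columns):
                raise ValueError("calls must have the same shape as signals")
            present = set(self.calls.stack().dropna().unique())
            bad = present - set(DETECTION_CALLS)
            if bad:
                raise ValueError(f"unknown detection calls: {sorted(bad)}")
        # align metadata row order with signal column order
        self.samples = self.samples.loc[list(self.signals.columns)]

    @property
    def probe_ids(self) -> pd.Index:
        return self.signals.index

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.samples["tissue"]:
            seen.setdefault(t, None)
        return list(seen)

    def samples_of(self, tissue: str) -> list[str]:
        mask = self.samples["tissue"] == tissue
        if not mask.any():
            raise ValueError(f"tissue {tissue!r} has no samples")
        return list(self.samples.index[mask])


@dataclass
class TissueProfile:
    """Per-probe, per-tissue aggregated signal and detection evidence."""

    mean_signal: pd.DataFrame
    present_fraction: pd.DataFrame
    n_replicates: pd.DataFrame
    gene_symbols: pd.Series

    def __post_init__(self) -> None:
        pf = self.present_fraction.to_numpy(dtype=float)
        ok = np.isnan(pf) | ((pf >= 0.0) & (pf <= 1.0))
        if not ok.all():
            raise ValueError("present_fraction outside [0, 1]")
        defined = ~self.mean_signal.isna()
        if (self.n_replicates.where(defined, other=1) < 1).any().any():
            raise ValueError("non-missing cells require n_replicates >= 1")

    @property
    def tissues(self) -> list[str]:
        return list(self.mean_signal.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.mean_signal.index

    def gene_level_signal(self, tissues: Sequence[str] | None = None) -> pd.DataFrame:
        """Collapse probes to gene symbols by per-tissue maximum.

        Multiple probe sets can interrogate one gene; the maximum keeps the
        "abundantly expressed" reading of a gene intact.
        """
        cols = list(tissues) if tissues is not None else self.tissues
        df = self.mean_signal[cols].copy()
        df["gene_symbol"] = self.gene_symbols
        return df.groupby("gene_symbol", sort=True).max()


@dataclass
class EnrichmentTable:
    """Per-probe, per-tissue fold change versus a reference tissue.

    ``fold_change`` cells are positive where defined and NaN where either
    operand was missing; the reference column is identically 1 by definition.
    """

    fold_change: pd.DataFrame
    gene_symbols: pd.Series
    reference_tissue: str
    floor: float

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError(f"floor must be positive, got {self.floor}")
        vals = self.fold_change.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("defined fold changes must be positive")

    @property
    def tissues(self) -> list[str]:
        return list(self.fold_change.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.fold_change.index

    def gene_level(self, tissues: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-gene fold change: per-tissue maximum across a symbol's probes."""
        cols = list(tissues) if tissues is not None else self.tissues
        df = self.fold_change[cols].copy()
        df["gene_symbol"] = self.gene_symbols
        return df.groupby("gene_symbol", sort=True).max()


@dataclass
class GeneList:
    """A curated, ordered gene list with class and optional family labels."""

    entries: pd.DataFrame  # columns: gene_symbol, class_label, family_label

    def __post_init__(self) -> None:
        for col in ("gene_symbol", "class_label"):
            if col not in self.entries.columns:
                raise ValueError(f"gene list lacks column {col!r}")
        if "family_label" not in self.entries.columns:
            self.entries = self.entries.assign(family_label="")
        self.entries = self.entries.reset_index(drop=True)
        cl = self.entries["class_label"].astype(str)
        if (cl.str.len() == 0).any() or cl.isna().any():
            raise ValueError("class_label must be non-empty for every entry")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.entries["class_label"]:
            seen.setdefault(c, None)
        return list(seen)

    def subset(self, class_label: str) -> "GeneList":
        sub = self.entries[self.entries["class_label"] == class_label]
        if sub.empty:
            raise ValueError(f"no entries with class {class_label!r}")
        return GeneList(sub.copy())

    def family(self, family_label: str) -> list[str]:
        sub = self.entries[self.entries["family_label"] == family_label]
        symbols: dict[str, None] = {}
        for s in sub["gene_symbol"]:
            symbols.setdefault(s, None)
        return list(symbols)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                       na_values=[""], comment=None)


def read_atlas(signal_path, meta_path, calls_path=None) -> AtlasMatrix:
    """Read an atlas from tab-separated signal, metadata and (optional) call files.

    The signal file has ``probe_id`` and ``gene_symbol`` columns followed by
    one column per sample; the metadata file has one row per sample with
    ``sample_id``, ``tissue``, ``life_stage`` and ``replicate`` columns.
    Blank signal cells become missing (NaN), never zero.
    """
    raw = _read_tsv(signal_path)
    if "probe_id" not in raw.columns or "gene_symbol" not in raw.columns:
        raise ValueError("signal file must have probe_id and gene_symbol columns")
    meta = _read_tsv(meta_path)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata file must have a sample_id column")
    meta = meta.set_index("sample_id")
    meta["replicate"] = meta["replicate"].astype(int)

    sample_cols = [c for c in raw.columns if c not in ("probe_id", "gene_symbol")]
    signals = raw[sample_cols].astype(float)
    signals.index = pd.Index(raw["probe_id"], name="probe_id")
    gene_symbols = pd.Series(
        raw["gene_symbol"].to_numpy(), index=signals.index, name="gene_symbol"
    )

    calls = None
    if calls_path is not None:
        craw = _read_tsv(calls_path)
        if "probe_id" not in craw.columns:
            raise ValueError("calls file must have a probe_id column")
        craw = craw.set_index("probe_id")
        craw = craw.drop(columns=[c for c in ("gene_symbol",) if c in craw.columns])
        calls = craw.reindex(index=signals.index, columns=signals.columns)

    return AtlasMatrix(signals=signals, gene_symbols=gene_symbols,
                       samples=meta, calls=calls)


def read_gene_list(path) -> GeneList:
    df = _read_tsv(path).fillna("")
    return GeneList(df)


# ---------------------------------------------------------------------------
# result-table serialization
#
# One TSV dialect for all three result kinds: tab-separated, UTF-8, '.'
# decimal, no quoting.  Leading '#key=value' lines carry the metadata needed
# to reconstruct the object; numbers are written at 6 significant digits and
# re-reading reproduces them bit-identically at that precision.
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if isinstance(x, (bool, np.bool_)):
        return "pass" if x else "fail"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return format(float(x), ".6g")
    return str(x)


def _frame_to_tsv(df: pd.DataFrame, header_meta: dict, path) -> None:
    lines = [f"#{k}={v}" for k, v in header_meta.items()]
    lines.append("\t".join(df.columns))
    for _, row in df.iterrows():
        lines.append("\t".join(_fmt(v) for v in row))
    text = "\n".join(lines) + "\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def write_table(result, path, tissue_order: Sequence[str] | None = None) -> None:
    """Serialize a TissueProfile, EnrichmentTable or SignatureResult to TSV.

    Column order is deterministic: ``probe_id``, ``gene_symbol``, then tissues
    in the given (or stored) order.  ``read_table`` reconstructs the object.
    """
    from .signatures import SignatureResult  # local import, avoids cycle

    if isinstance(result, TissueProfile):
        tissues = list(tissue_order) if tissue_order else result.tissues
        df = pd.DataFrame({"probe_id": result.probe_ids,
                           "gene_symbol": result.gene_symbols.to_numpy()})
        for t in tissues:
            df[f"mean__{t}"] = result.mean_signal[t].to_numpy()
        for t in tissues:
            df[f"pf__{t}"] = result.present_fraction[t].to_numpy()
        for t in tissues:
            df[f"n__{t}"] = result.n_replicates[t].to_numpy()
        _frame_to_tsv(df, {"type": "profile"}, path)
    elif isinstance(result, EnrichmentTable):
        tissues = list(tissue_order) if tissue_order else result.tissues
        df = pd.DataFrame({"probe_id": result.probe_ids,
                           "gene_symbol": result.gene_symbols.to_numpy()})
        for t in tissues:
            df[t] = result.fold_change[t].to_numpy()
        meta = {"type": "enrichment",
                "reference_tissue": result.reference_tissue,
                "floor": _fmt(result.floor)}
        _frame_to_tsv(df, meta, path)
    elif isinstance(result, SignatureResult):
        tissues = list(result.tissues)
        df = pd.DataFrame({"probe_id": result.table.index,
                           "gene_symbol": result.table["gene_symbol"].to_numpy()})
        for t in tissues:
            df[t] = result.table[t].to_numpy()
        for t in tissues:
            df[f"pass__{t}"] = result.table[f"pass__{t}"].to_numpy()
        df["overall_pass"] = result.table["overall_pass"].to_numpy()
        meta = {"type": "signature", "mode": result.mode,
                "tissues": ",".join(tissues),
                "criterion": json.dumps(result.criterion, sort_keys=True)}
        _frame_to_tsv(df, meta, path)
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")


def _split_meta(path) -> tuple[dict, pd.DataFrame]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#") and not body_lines:
            k, _, v = line[1:].partition("=")
            meta[k] = v
        else:
            body_lines.append(line)
    body = "\n".join(body_lines)
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str,
                     keep_default_na=False, na_values=[""])
    return meta, df


def read_table(path):
    """Inverse of :func:`write_table`; dispatches on the ``#type`` header."""
    from .signatures import SignatureResult

    meta, df = _split_meta(path)
    kind = meta.get("type")
    idx = pd.Index(df["probe_id"], name="probe_id")
    symbols = pd.Series(df["gene_symbol"].to_numpy(), index=idx,
                        name="gene_symbol")
    if kind == "profile":
        tissues = [c[len("mean__"):] for c in df.columns if c.startswith("mean__")]
        mean = pd.DataFrame({t: df[f"mean__{t}"].astype(float).to_numpy()
                             for t in tissues}, index=idx)
        pf = pd.DataFrame({t: df[f"pf__{t}"].astype(float).to_numpy()
                           for t in tissues}, index=idx)
        n = pd.DataFrame({t: df[f"n__{t}"].astype(float).to_numpy()
                          for t in tissues}, index=idx).fillna(0).astype(int)
        return TissueProfile(mean, pf, n, symbols)
    if kind == "enrichment":
        tissues = [c for c in df.columns
                   if c not in ("probe_id", "gene_symbol")]
        fc = pd.DataFrame({t: df[t].astype(float).to_numpy() for t in tissues},
                          index=idx)
        return EnrichmentTable(fc, symbols, meta["reference_tissue"],
                               float(meta["floor"]))
    if kind == "signature":
        tissues = meta["tissues"].split(",") if meta.get("tissues") else []
        table = pd.DataFrame(index=idx)
        table["gene_symbol"] = symbols
        for t in tissues:
            table[t] = df[t].astype(float).to_numpy()
        for t in tissues:
            table[f"pass__{t}"] = (df[f"pass__{t}"] == "pass").to_numpy()
        table["overall_pass"] = (df["overall_pass"] == "pass").to_numpy()
        return SignatureResult(mode=meta["mode"], table=table,
                               criterion=json.loads(meta["criterion"]),
                               tissues=tuple(tissues))
    raise ValueError(f"unrecognized table type {kind!r} in {path}")
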
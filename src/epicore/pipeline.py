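"""Orchestration: one configured run chaining both analysis branches.

A run executes the hypothesis-free branch (enrichment -> consensus core +
per-tissue top-N + strict-call alternative) and the hypothesis-led branch
(curated-list profiling + dominant isoforms) on one atlas — simulated or
read from files — followed by the structure checks (hierarchical clustering
and PCA with group cohesion).  Every output is written under an output
directory and recorded, with its SHA-256 digest, in a :class:`RunManifest`;
identical config and seed reproduce identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .atlas import (
    AnalysisConfig,
    COGNATE_PAIRS,
    read_atlas,
    read_gene_list,
    write_table,
)
from .clustering import group_cohesion, hcluster_tissues, pca_tissues
from .enrichment import aggregate_replicates, fold_change
from .signatures import (
    core_signature,
    criterion_audit,
    profile_gene_list,
    strict_call_signature,
    tissue_specific_top_n,
)
from .simulate import SimConfig, evaluate_recovery, generate_atlas

__all__ = ["RunManifest", "run_pipeline", "render_report", "validate_config"]

log = logging.getLogger("epicore")

_ANALYSIS_KEYS = {"epithelial_tissues", "reference_tissue", "tau", "top_n",
                  "floor", "aggregation", "rng_seed"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)} - {"tissues"}


def validate_config(config: dict) -> dict:
    """Validate a pipeline config document and fill defaults.

    Schema (one JSON object)::

        {
          "input":    {"mode": "simulate"} |
                      {"mode": "files", "signals": ..., "meta": ...,
                       "calls": ... (optional)},
          "sim":      {SimConfig field overrides},          # optional
          "analysis": {AnalysisConfig field overrides},     # optional
          "gene_list": path,                                # optional
          "cluster_group": [tissue, ...] | "epithelial"     # optional
        }
    """
    if not isinstance(config, dict):
        raise ValueError("config must be a JSON object")
    cfg = dict(config)
    inp = dict(cfg.get("input", {"mode": "simulate"}))
    mode = inp.get("mode")
    if mode not in ("simulate", "files"):
        raise ValueError(f"input.mode must be 'simulate' or 'files', got {mode!r}")
    if mode == "files":
        for key in ("signals", "meta"):
            if key not in inp:
                raise ValueError(f"input.{key} is required in files mode")
    sim = dict(cfg.get("sim", {}))
    bad = set(sim) - _SIM_KEYS
    if bad:
        raise ValueError(f"unknown sim keys: {sorted(bad)}")
    analysis = dict(cfg.get("analysis", {}))
    bad = set(analysis) - _ANALYSIS_KEYS
    if bad:
        raise ValueError(f"unknown analysis keys: {sorted(bad)}")
    AnalysisConfig.from_dict(analysis)  # raises on invalid values
    group = cfg.get("cluster_group", "epithelial")
    if group != "epithelial" and not (
        isinstance(group, list) and all(isinstance(t, str) for t in group)
    ):
        raise ValueError("cluster_group must be 'epithelial' or a tissue list")
    cfg["input"], cfg["sim"], cfg["analysis"] = inp, sim, analysis
    cfg["cluster_group"] = group
    return cfg


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    rng_seed: int
    config: dict
    started: str
    finished: str | None = None
    stages: list = dataclasses.field(default_factory=list)
    failed_stage: str | None = None

    def record(self, stage: str, outputs: dict[str, str],
               counts: dict | None = None) -> None:
        self.stages.append({"stage": stage, "outputs": outputs,
                            "counts": counts or {}})

    def output_digests(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in self.stages:
            out.update(s["outputs"])
        return out

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def verify(self) -> None:
        """Re-hash every recorded output; raise on a missing or altered file."""
        for path, digest in self.output_digests().items():
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"manifest output missing: {path}")
            if _sha256(p) != digest:
                raise ValueError(f"manifest digest mismatch for {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stamp() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Execute the full workflow described by *config* into *out_dir*.

    Any stage failure aborts with the stage name attached; outputs written
    before the failure stay recorded in the (partial) manifest.
    """
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = json.load(fh)
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    analysis = AnalysisConfig.from_dict(cfg["analysis"])
    if seed is not None:
        analysis = analysis.replace(rng_seed=int(seed))
    manifest = RunManifest(version=__version__, rng_seed=analysis.rng_seed,
                           config=cfg, started=_stamp())

    stage = "setup"
    try:
        # ingest -----------------------------------------------------------
        truth = None
        if cfg["input"]["mode"] == "simulate":
            stage = "simulate"
            sim = SimConfig(**{**cfg["sim"], "rng_seed": analysis.rng_seed})
            atlas, truth = generate_atlas(sim)
            truth_path = out / "truth.tsv"
            truth.to_csv(truth_path, sep="\t")
            manifest.record(stage, {str(truth_path): _sha256(truth_path)},
                            {"n_genes": len(atlas.probe_ids),
                             "n_samples": len(atlas.samples)})
            log.info("simulate: %d genes x %d samples",
                     len(atlas.probe_ids), len(atlas.samples))
        else:
            stage = "ingest"
            atlas = read_atlas(cfg["input"]["signals"], cfg["input"]["meta"],
                               cfg["input"].get("calls"))
            manifest.record(stage, {}, {"n_genes": len(atlas.probe_ids),
                                        "n_samples": len(atlas.samples)})

        analysis.check_tissues(atlas.tissues)

        # aggregate + enrich ----------------------------------------------
        stage = "aggregate"
        profile = aggregate_replicates(atlas, analysis)
        profile_path = out / "profile.tsv"
        write_table(profile, profile_path)
        manifest.record(stage, {str(profile_path): _sha256(profile_path)},
                        {"n_tissues": len(profile.tissues)})

        stage = "enrich"
        enrichment = fold_change(profile, analysis)
        enr_path = out / "enrichment.tsv"
        write_table(enrichment, enr_path)
        manifest.record(stage, {str(enr_path): _sha256(enr_path)})

        # hypothesis-free branch ------------------------------------------
        stage = "core"
        core = core_signature(enrichment, analysis)
        core_path = out / "core_signature.tsv"
        write_table(core, core_path)
        audit = criterion_audit(core, analysis,
                                published=core.pass_probes)
        audit_path = out / "core_audit.tsv"
        audit.to_csv(audit_path, sep="\t", index=False)
        report_path = out / "core_report.tsv"
        report_path.write_text(render_report(core, style="table2"),
                               encoding="utf-8")
        manifest.record(stage, {str(p): _sha256(p) for p in
                                (core_path, audit_path, report_path)},
                        {"n_in": len(core), "n_pass": len(core.pass_probes)})
        log.info("core: %d/%d genes pass tau=%g",
                 len(core.pass_probes), len(core), analysis.tau)

        stage = "strict"
        strict = strict_call_signature(profile, analysis)
        strict_path = out / "strict_signature.tsv"
        write_table(strict, strict_path)
        manifest.record(stage, {str(strict_path): _sha256(strict_path)},
                        {"n_pass": len(strict.pass_probes)})

        stage = "specific"
        outputs = {}
        topn_counts = {}
        merged = {a: b for a, b in COGNATE_PAIRS}
        for tissue in analysis.epithelial_tissues:
            top = tissue_specific_top_n(enrichment, tissue, analysis)
            p = out / f"top{analysis.top_n}_{tissue}.tsv"
            write_table(top, p)
            outputs[str(p)] = _sha256(p)
            topn_counts[tissue] = len(top)
        for adult, larval in merged.items():
            if adult in analysis.epithelial_tissues and \
                    larval in analysis.epithelial_tissues:
                top = tissue_specific_top_n(enrichment, adult, analysis,
                                            merge_with=larval)
                p = out / f"top{analysis.top_n}_{adult}_merged.tsv"
                write_table(top, p)
                outputs[str(p)] = _sha256(p)
        manifest.record(stage, outputs, topn_counts)

        # hypothesis-led branch -------------------------------------------
        if cfg.get("gene_list"):
            stage = "profile_genelist"
            genes = read_gene_list(cfg["gene_list"])
            mapped = profile_gene_list(profile, genes, analysis)
            p = out / "gene_list_profile.tsv"
            mapped.to_csv(p, sep="\t", index=False, float_format="%.6g")
            manifest.record(stage, {str(p): _sha256(p)},
                            {"n_rows": len(mapped)})

        # structure checks ------------------------------------------------
        stage = "cluster"
        cluster_tissues = [t for t in profile.tissues
                           if t != analysis.reference_tissue]
        dend = hcluster_tissues(profile, cluster_tissues)
        newick_path = out / "dendrogram.nwk"
        newick_path.write_text(dend.to_newick() + "\n", encoding="utf-8")
        k = min(5, len(cluster_tissues) - 1)
        pca = pca_tissues(profile, k, tissues=cluster_tissues)
        scores_path = out / "pca_scores.tsv"
        pca.scores.to_csv(scores_path, sep="\t", float_format="%.6g")
        group = cfg["cluster_group"]
        if group == "epithelial":
            group = list(analysis.epithelial_tissues)
        cohesion = group_cohesion(group, pca=pca, dendrogram=dend)
        coh_path = out / "cohesion.json"
        coh_path.write_text(json.dumps({
            "group": list(cohesion.group),
            "silhouette": cohesion.silhouette,
            "is_subtree": cohesion.is_subtree}, indent=2), encoding="utf-8")
        manifest.record(stage, {str(p): _sha256(p) for p in
                                (newick_path, scores_path, coh_path)})

        # recovery (synthetic runs only) ----------------------------------
        if truth is not None:
            stage = "recovery"
            rec = evaluate_recovery(core, truth, "core")
            p = out / "recovery.json"
            p.write_text(json.dumps(rec.as_dict(), indent=2), encoding="utf-8")
            manifest.record(stage, {str(p): _sha256(p)}, rec.as_dict())
            log.info("recovery: precision=%.3f recall=%.3f",
                     rec.precision, rec.recall)
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.finished = _stamp()
        (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = _stamp()
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest


def render_report(result, style: str, descriptions: pd.Series | None = None,
                  top_n: int | None = None) -> str:
    """Render a result as a publication-style text table.

    ``table2``: one row per gene with its per-epithelium fold changes, a
    description placeholder and the pass flag.  ``table1``: a class-grouped
    signal matrix (expects the frame from :func:`profile_gene_list`).
    ``topn``: rank / gene / enrichment, at most N rows.
    """
    if style == "table2":
        tissues = list(result.tissues)
        lines = ["\t".join(["gene_symbol", *tissues, "description", "pass"])]
        for pid, row in result.table.iterrows():
            desc = ""
            if descriptions is not None and pid in descriptions.index:
                desc = str(descriptions[pid])
            cells = [row["gene_symbol"]]
            cells += [format(float(row[t]), ".6g") if pd.notna(row[t]) else ""
                      for t in tissues]
            cells += [desc, "pass" if row["overall_pass"] else "fail"]
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"
    if style == "table1":
        df = result
        tissues = [c for c in df.columns if c not in
                   ("class_label", "family_label", "gene_symbol",
                    "probe_id", "in_atlas")]
        lines = ["\t".join(["gene_symbol", *tissues])]
        for cls in dict.fromkeys(df["class_label"]):
            lines.append(f"## {cls}")
            for _, row in df[df["class_label"] == cls].iterrows():
                cells = [row["gene_symbol"]]
                if not row["in_atlas"]:
                    cells += ["missing"] * len(tissues)
                else:
                    cells += [format(float(row[t]), ".6g")
                              if pd.notna(row[t]) else "" for t in tissues]
                lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"
    if style == "topn":
        label = result.tissues[0]
        n = top_n if top_n is not None else len(result.table)
        lines = ["\t".join(["rank", "gene_symbol", "enrichment"])]
        for rank, (_, row) in enumerate(result.table.head(n).iterrows(), 1):
            lines.append(f"{rank}\t{row['gene_symbol']}\t"
                         f"{format(float(row[label]), '.6g')}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report style {style!r}")
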
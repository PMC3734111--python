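"""Synthetic expression-atlas generator with planted ground truth.

The generator emulates the statistical structure of an Affymetrix multi-
tissue atlas: strictly positive, heavily right-skewed signals spanning
roughly 0-14,000 units; four biological replicates per tissue with
multiplicative log-normal noise; detection calls thresholded on signal; and
four planted gene classes —

* ``housekeeping`` — abundant everywhere, damped tissue effects;
* ``core`` — enriched by a planted fold change in *all* epithelial tissues;
* ``specific`` — enriched in one target organ only (both life stages);
* ``background`` — baseline expression with ordinary tissue variation.

Tissue structure is hierarchical: all epithelial tissues share a per-gene
"epithelial program" effect, each organ (a cognate adult/larval pair, or a
singleton like brain) shares a per-gene organ effect, and each tissue adds a
stage-specific perturbation.  Planted fold changes are applied to the tissue
mean *before* replicate noise, so the noise-free limit is analytically exact:
with CV = 0 and a vanishing floor, the recovered fold change of a core gene
equals its planted value in every epithelial tissue, exactly.

The whole-organism reference tissue carries the per-gene baseline with no
tissue effect, standing in for a signal averaged over the whole animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import AtlasMatrix, DEFAULT_REFERENCE

__all__ = [
    "TissueSpec",
    "SimConfig",
    "RecoveryReport",
    "default_tissue_panel",
    "generate_atlas",
    "evaluate_recovery",
]

GENE_CLASSES = ("housekeeping", "core", "specific", "background")


@dataclass(frozen=True)
class TissueSpec:
    """One simulated tissue: its organ, life stage and epithelial status."""

    name: str
    organ: str
    life_stage: str  # adult | larval | whole | other
    is_epithelial: bool


def default_tissue_panel() -> tuple[TissueSpec, ...]:
    """Eleven tissues: four cognate epithelial organ pairs, brain, testis,
    and a whole-organism reference."""
    panel = []
    for organ in ("salivary_gland", "midgut", "tubule", "hindgut"):
        panel.append(TissueSpec(f"adult_{organ}", organ, "adult", True))
        panel.append(TissueSpec(f"larval_{organ}", organ, "larval", True))
    panel.append(TissueSpec("brain", "brain", "adult", False))
    panel.append(TissueSpec("testis", "testis", "adult", False))
    panel.append(TissueSpec(DEFAULT_REFERENCE, "whole", "whole", False))
    return tuple(panel)


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Effect sizes are on the log2-signal scale.  ``organ_effect_sd`` versus
    ``stage_effect_sd`` sets the cognate-pair correlation strength: the organ
    effect is shared by the adult and larval members of a pair, the stage
    effect is not.
    """

    n_genes: int = 2000
    tissues: tuple[TissueSpec, ...] = field(default_factory=default_tissue_panel)
    n_replicates: int = 4
    p_housekeeping: float = 0.10
    p_core: float = 0.025
    p_specific: float = 0.06
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.5
    housekeeping_log2_mean: float = 10.0
    housekeeping_log2_sd: float = 1.0
    housekeeping_damping: float = 0.25
    core_fc_range: tuple[float, float] = (3.0, 10.0)
    specific_fc_range: tuple[float, float] = (10.0, 100.0)
    epithelial_effect_sd: float = 0.4
    organ_effect_sd: float = 0.35
    stage_effect_sd: float = 0.2
    replicate_cv: float = 0.2
    detection_threshold: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")
        p_bg = 1.0 - self.p_housekeeping - self.p_core - self.p_specific
        probs = (self.p_housekeeping, self.p_core, self.p_specific, p_bg)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"class proportions invalid: {probs}")
        for lo, hi in (self.core_fc_range, self.specific_fc_range):
            if not (0 < lo <= hi):
                raise ValueError("fold-change ranges must be positive")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tissue names")

    @property
    def p_background(self) -> float:
        return 1.0 - self.p_housekeeping - self.p_core - self.p_specific

    @property
    def epithelial_tissues(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tissues if t.is_epithelial)

    @property
    def organs(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.tissues:
            if t.life_stage != "whole":
                seen.setdefault(t.organ, None)
        return tuple(seen)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _class_labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_genes
    n_hk = int(round(config.p_housekeeping * n))
    n_core = int(round(config.p_core * n))
    n_spec = int(round(config.p_specific * n))
    if n_hk + n_core + n_spec > n:
        raise ValueError("class proportions exceed the gene count")
    labels = np.array(
        ["core"] * n_core + ["housekeeping"] * n_hk + ["specific"] * n_spec
        + ["background"] * (n - n_hk - n_core - n_spec), dtype=object)
    return labels


def generate_atlas(config: SimConfig,
                   seed: int | None = None) -> tuple[AtlasMatrix, pd.DataFrame]:
    """Draw an atlas and its ground truth.

    Returns the replicate-level :class:`AtlasMatrix` (with detection calls)
    and a ``SyntheticTruth`` frame indexed by probe_id with ``class_label``,
    ``planted_fc`` (1 for non-enriched classes) and ``target_organ``
    (specific class only).  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    n = config.n_genes
    classes = _class_labels(config, rng)
    is_hk = classes == "housekeeping"
    is_core = classes == "core"
    is_spec = classes == "specific"

    base = np.where(
        is_hk,
        rng.normal(config.housekeeping_log2_mean, config.housekeeping_log2_sd, n),
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n),
    )
    core_fc = rng.uniform(*config.core_fc_range, n)
    spec_fc = rng.uniform(*config.specific_fc_range, n)
    target_organ = rng.choice(np.array(config.organs, dtype=object), n)

    epi_eff = rng.normal(0.0, config.epithelial_effect_sd, n)
    organ_eff = {o: rng.normal(0.0, config.organ_effect_sd, n)
                 for o in config.organs}
    stage_eff = {t.name: rng.normal(0.0, config.stage_effect_sd, n)
                 for t in config.tissues if t.life_stage != "whole"}
    damp = np.where(is_hk, config.housekeeping_damping, 1.0)

    # Planted fold changes multiply the *linear* baseline signal, so in the
    # noise-free limit the recovered ratio equals the planted value exactly
    # (bit-exact for power-of-two fold changes).
    base_lin = np.exp2(base)
    tissue_mean = {}
    for t in config.tissues:
        if t.life_stage == "whole":
            col = base_lin.copy()
        else:
            eff = organ_eff[t.organ] + stage_eff[t.name]
            if t.is_epithelial:
                eff = eff + epi_eff
            col = np.exp2(base + damp * eff)
            if t.is_epithelial:
                col = np.where(is_core, base_lin * core_fc, col)
            col = np.where(is_spec & (target_organ == t.organ),
                           base_lin * spec_fc, col)
        tissue_mean[t.name] = col

    probe_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="probe_id")
    sigma = float(np.sqrt(np.log1p(config.replicate_cv ** 2)))
    signal_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for t in config.tissues:
        mean = tissue_mean[t.name]
        for r in range(1, config.n_replicates + 1):
            if sigma > 0:
                noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, n)
            else:
                noise = np.ones(n)
            sid = f"{t.name}__r{r}"
            signal_cols[sid] = mean * noise
            meta_rows.append({"sample_id": sid, "tissue": t.name,
                              "life_stage": t.life_stage, "replicate": r})
    signals = pd.DataFrame(signal_cols, index=probe_ids)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")

    thr = config.detection_threshold
    vals = signals.to_numpy()
    call_arr = np.where(vals >= thr, "P", np.where(vals >= thr / 2.0, "M", "A"))
    calls = pd.DataFrame(call_arr, index=probe_ids, columns=signals.columns)

    gene_symbols = pd.Series(probe_ids.to_numpy(), index=probe_ids,
                             name="gene_symbol")
    atlas = AtlasMatrix(signals=signals, gene_symbols=gene_symbols,
                        samples=samples, calls=calls)
    truth = pd.DataFrame(
        {"class_label": classes,
         "planted_fc": np.where(is_core, core_fc,
                                np.where(is_spec, spec_fc, 1.0)),
         "target_organ": np.where(is_spec, target_organ, "")},
        index=probe_ids)
    return atlas, truth


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of a detected gene set against planted truth."""

    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int
    no_detections: bool

    def as_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "no_detections": self.no_detections}


def evaluate_recovery(detected, truth: pd.DataFrame,
                      target_class: str = "core") -> RecoveryReport:
    """Compare a detected gene set with the planted class membership.

    *detected* is a SignatureResult or any iterable of probe ids; it must
    draw from the truth's gene universe.  Precision is 0 (flagged) when
    nothing was detected.
    """
    if target_class not in GENE_CLASSES:
        raise ValueError(f"unknown target class {target_class!r}")
    if hasattr(detected, "pass_probes"):
        det = set(detected.pass_probes)
    else:
        det = set(detected)
    universe = set(truth.index)
    stray = det - universe
    if stray:
        raise ValueError(f"detected ids outside the truth universe: "
                         f"{sorted(stray)[:5]}")
    pos = set(truth.index[truth["class_label"] == target_class])
    tp = len(det & pos)
    fp = len(det - pos)
    fn = len(pos - det)
    tn = len(universe) - tp - fp - fn
    no_det = len(det) == 0
    precision = 0.0 if no_det else tp / (tp + fp)
    recall = 0.0 if not pos else tp / (tp + fn)
    return RecoveryReport(precision, recall, tp, fp, fn, tn, no_det)
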
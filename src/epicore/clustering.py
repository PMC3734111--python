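"""Structure checks on tissue transcriptomes: correlation-distance
hierarchical clustering and PCA, with a group-cohesion report.

Distances are ``1 - Pearson r`` of log2(signal + 1) profiles — the standard
scale-free choice for transcriptomes — and trees use average linkage.  PCA
operates on centered log2 tissue-mean profiles ("grouped replicates"); a
replicate-level mode is available for atlases.  Component signs are fixed by
making each component's largest-magnitude gene loading positive, so outputs
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from skbio import TreeNode
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .atlas import AtlasMatrix, TissueProfile

__all__ = [
    "Dendrogram",
    "PcaResult",
    "CohesionReport",
    "tissue_distance",
    "distance_matrix",
    "hcluster_tissues",
    "pca_tissues",
    "group_cohesion",
]


def _log_matrix(profile: TissueProfile,
                tissues: Sequence[str] | None = None) -> pd.DataFrame:
    """Tissues x genes matrix of log2(mean signal + 1), complete genes only."""
    cols = list(tissues) if tissues is not None else profile.tissues
    sub = profile.mean_signal[cols].dropna(axis=0, how="any")
    return np.log2(sub + 1.0).T


def tissue_distance(profile: TissueProfile, t1: str, t2: str,
                    transform: str = "log2p1") -> float:
    """Correlation distance between two tissue profiles.

    ``1 - Pearson r`` of log2(signal + 1) over the genes defined in both
    tissues; lies in [0, 2].  Requires at least 3 shared genes.
    """
    if transform != "log2p1":
        raise ValueError(f"unknown transform {transform!r}")
    for t in (t1, t2):
        if t not in profile.tissues:
            raise ValueError(f"tissue {t!r} not in profile")
    pair = profile.mean_signal[[t1, t2]].dropna(axis=0, how="any")
    if len(pair) < 3:
        raise ValueError(
            f"need >= 3 genes defined in both tissues, have {len(pair)}")
    x = np.log2(pair[t1].to_numpy() + 1.0)
    y = np.log2(pair[t2].to_numpy() + 1.0)
    r = np.corrcoef(x, y)[0, 1]
    return float(np.clip(1.0 - r, 0.0, 2.0))


def distance_matrix(profile: TissueProfile,
                    tissues: Sequence[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of pairwise tissue distances (zero diagonal)."""
    cols = list(tissues) if tissues is not None else profile.tissues
    n = len(cols)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tissue_distance(profile, cols[i], cols[j])
    return pd.DataFrame(d, index=cols, columns=cols)


@dataclass
class Dendrogram:
    """Binary merge tree over tissue leaves with non-negative merge heights."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("a dendrogram needs >= 2 leaves")
        if self.linkage.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cluster_leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-label set of every node (leaves, then internal merges)."""
        n = len(self.labels)
        sets: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        out = list(sets.values())
        for k, (a, b, _h, _c) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def is_sibling_pair(self, t1: str, t2: str) -> bool:
        """True iff some merge joins exactly the singleton leaves t1 and t2."""
        return frozenset([t1, t2]) in set(self.cluster_leaf_sets())

    def is_connected_subtree(self, group: Sequence[str]) -> bool:
        """True iff *group* is exactly the leaf set of some tree node."""
        target = frozenset(group)
        if not target <= set(self.labels):
            raise ValueError("group contains unknown tissues")
        return target in set(self.cluster_leaf_sets())

    def to_tree(self) -> TreeNode:
        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.labels))
        # from_linkage_matrix stores cumulative heights; convert to branch
        # lengths = height differences so the tree is ultrametric.
        return tree

    def to_newick(self) -> str:
        return str(self.to_tree()).strip()


def hcluster_tissues(profile: TissueProfile,
                     tissues: Sequence[str] | None = None,
                     linkage: str = "average") -> Dendrogram:
    """Average-linkage agglomeration of tissues on correlation distance.

    Tissues are processed in lexicographic name order, which makes equal-
    distance merges deterministic.
    """
    cols = list(tissues) if tissues is not None else profile.tissues
    if len(cols) < 2:
        raise ValueError("need at least 2 tissues to cluster")
    cols = sorted(cols)
    dmat = distance_matrix(profile, cols)
    condensed = squareform(dmat.to_numpy(), checks=False)
    Z = sch.linkage(condensed, method=linkage)
    return Dendrogram(tuple(cols), Z)


@dataclass
class PcaResult:
    """Tissue scores and explained-variance fractions of a profile PCA."""

    scores: pd.DataFrame          # tissues x components
    explained_variance_ratio: np.ndarray
    components: pd.DataFrame      # components x genes (loadings)
    mean: pd.Series               # per-gene centering offsets

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if (evr < -1e-12).any() or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions invalid")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        """Centered-data reconstruction from all retained components."""
        X = self.scores.to_numpy() @ self.components.to_numpy()
        return pd.DataFrame(X, index=self.scores.index,
                            columns=self.components.columns)


def pca_tissues(profile: TissueProfile | None, k: int,
                tissues: Sequence[str] | None = None,
                atlas: AtlasMatrix | None = None) -> PcaResult:
    """PCA of centered log2(signal + 1) tissue vectors.

    By default one vector per tissue (mean profile); passing *atlas* instead
    switches to replicate-level vectors, one per sample.  The sign of each
    component is fixed by making its largest-magnitude loading positive.
    """
    if atlas is not None:
        sub = atlas.signals.dropna(axis=0, how="any")
        X = np.log2(sub + 1.0).T  # samples x genes
    elif profile is not None:
        X = _log_matrix(profile, tissues)
    else:
        raise ValueError("provide a profile or an atlas")
    n = X.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy())
    comps = pca.components_
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            scores[:, i] *= -1.0
    pc_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=pc_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        components=pd.DataFrame(comps, index=pc_names, columns=X.columns),
        mean=pd.Series(pca.mean_, index=X.columns),
    )


@dataclass
class CohesionReport:
    """How distinctly a tissue group separates from the remaining tissues."""

    group: tuple[str, ...]
    silhouette: float | None      # mean silhouette of the group in score space
    is_subtree: bool | None       # connected clade in the dendrogram


def group_cohesion(group: Sequence[str],
                   pca: PcaResult | None = None,
                   dendrogram: Dendrogram | None = None,
                   n_components: int = 2) -> CohesionReport:
    """Silhouette (in PCA score space) and subtree status of a tissue group."""
    group = list(group)
    if len(group) < 2:
        raise ValueError("group must contain at least 2 tissues")
    sil: float | None = None
    subtree: bool | None = None
    if pca is not None:
        tissues = list(pca.scores.index)
        unknown = [t for t in group if t not in tissues]
        if unknown:
            raise ValueError(f"group tissues not in PCA: {unknown}")
        labels = np.array([1 if t in set(group) else 0 for t in tissues])
        if labels.all():
            sil = 0.0  # group == all tissues: separation is undefined
        else:
            ncomp = min(n_components, pca.n_components)
            pts = pca.scores.to_numpy()[:, :ncomp]
            samp = silhouette_samples(pts, labels)
            sil = float(samp[labels == 1].mean())
    if dendrogram is not None:
        subtree = (set(group) == set(dendrogram.labels)
                   or dendrogram.is_connected_subtree(group))
    return CohesionReport(tuple(group), sil, subtree)
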
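"""Two-group classification of cells or cohort samples on module expression.

Samples are clustered on the module genes' log2 fold-change columns by
agglomerative hierarchical clustering (Euclidean distance, complete
linkage by default) and the tree is cut into exactly two groups; the
group with the higher mean module fold-change is labelled ``up``, the
other ``down``.  Principal-component coordinates of the same submatrix
are exported for inspection — with a well-separated module the first
component recapitulates the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression_io import FoldChangeMatrix
from .module_discovery import GeneModule


@dataclass
class SubgroupAssignment:
    """Per-sample up/down label with clustering provenance."""

    sample_ids: list[str]
    label: dict[str, str]
    linkage: str
    distance: str
    mean_module_fc: dict[str, float]
    leaf_order: list[str]

    def __post_init__(self) -> None:
        groups = set(self.label.values())
        if len(self.sample_ids) >= 2 and groups != {"up", "down"}:
            raise ValueError("expected exactly two non-empty groups up/down")
        up = [self.mean_module_fc[s] for s in self.sample_ids if self.label[s] == "up"]
        down = [self.mean_module_fc[s] for s in self.sample_ids if self.label[s] == "down"]
        if up and down and not np.mean(up) > np.mean(down):
            raise ValueError("'up' group must have greater mean module fold-change")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.label[s] == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": [self.label[s] for s in self.sample_ids],
                "mean_module_fc": [self.mean_module_fc[s] for s in self.sample_ids],
            }
        )


def module_fc_submatrix(fc: FoldChangeMatrix, module: GeneModule) -> FoldChangeMatrix:
    """Restrict a fold-change matrix to the module's member genes."""
    present = set(fc.gene_ids)
    missing = sorted(g for g in module.members if g not in present)
    if missing:
        raise KeyError(f"module genes absent from fold-change matrix: {missing[:10]}")
    keep = [g for g in fc.gene_ids if g in module.members]
    if not keep:
        raise KeyError("module does not intersect the fold-change matrix")
    return fc.subset_genes(keep)


def two_group_split(
    sub: FoldChangeMatrix,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> SubgroupAssignment:
    """Cut the sample dendrogram into two groups and label them up/down."""
    samples = sub.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    x = sub.values.to_numpy(dtype=float).T  # samples x genes
    d = pdist(x, metric=metric)
    if np.all(d == 0):
        raise ValueError("all sample columns are identical; no split exists")
    z = hierarchy.linkage(d, method=linkage)
    flat = hierarchy.fcluster(z, t=2, criterion="maxclust")
    mean_fc = {s: float(x[i].mean()) for i, s in enumerate(samples)}
    means = {
        k: np.mean([mean_fc[s] for s, c in zip(samples, flat) if c == k])
        for k in np.unique(flat)
    }
    up_cluster = max(means, key=lambda k: means[k])
    label = {s: ("up" if c == up_cluster else "down") for s, c in zip(samples, flat)}
    leaves = hierarchy.leaves_list(z)
    return SubgroupAssignment(
        sample_ids=list(samples),
        label=label,
        linkage=linkage,
        distance=metric,
        mean_module_fc=mean_fc,
        leaf_order=[samples[i] for i in leaves],
    )


def pca_coordinates(
    sub: FoldChangeMatrix, k: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA coordinates on mean-centred gene rows.

    Returns a (samples x k) coordinate table and the fractions of
    variance explained.  Component signs are fixed by forcing each
    component's largest-magnitude gene loading positive.
    """
    n_genes = len(sub.gene_ids)
    n_samples = len(sub.sample_ids)
    if not (1 <= k <= min(n_genes, n_samples)):
        raise ValueError(f"k must lie in [1, {min(n_genes, n_samples)}], got {k}")
    x = sub.values.to_numpy(dtype=float)
    centred = x - x.mean(axis=1, keepdims=True)
    # samples are observations, genes are features
    u, s, vt = np.linalg.svd(centred.T, full_matrices=False)
    total = float((s**2).sum())
    var_frac = (s**2) / total if total > 0 else np.zeros_like(s)
    coords = u * s
    for j in range(min(k, len(s))):
        loading = vt[j]
        i_max = int(np.argmax(np.abs(loading)))
        if loading[i_max] < 0:
            coords[:, j] *= -1
    table = pd.DataFrame(
        coords[:, :k],
        index=sub.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    table.index.name = "sample_id"
    return table, var_frac[:k]


def heatmap_export(
    sub: FoldChangeMatrix, assignment: SubgroupAssignment
) -> pd.DataFrame:
    """Module genes x samples table with columns in dendrogram leaf order."""
    return sub.values[assignment.leaf_order].copy()
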
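"""Seed-and-expand discovery of co-expressed gene modules.

Gene-gene Pearson correlations are computed over the cells' log2
fold-change profiles.  Genes forming connected components of the
high-correlation graph (r >= ``r_seed``, default 0.9) with at least
``min_seed_group`` members (default 5) are collected as seed genes;
the module is then expanded with every gene whose mean correlation to
the seed set reaches ``r_expand`` (default 0.75).  The strict seed
threshold picks out the most tightly co-regulated core; the looser
expansion threshold grows the module while keeping within-module
correlation high — dropping it further would enlarge the module at the
cost of coherence, which ``threshold_sweep`` quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .expression_io import FoldChangeMatrix


@dataclass
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation grid with unit diagonal."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation grid shape does not match gene_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation grid is not symmetric")
        if np.abs(self.values).max() > 1 + 1e-9:
            raise ValueError("correlation entries outside [-1, 1]")

    def index_of(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from correlation matrix: {missing}")
        return np.array([pos[g] for g in genes], dtype=int)


@dataclass
class GeneModule:
    """A seed gene set plus its expanded membership and the thresholds used."""

    seed_genes: set[str]
    members: set[str]
    r_seed: float = 0.9
    r_expand: float = 0.75
    min_seed_group: int = 5
    mean_r_to_seeds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seed_genes <= self.members:
            raise ValueError("seed genes must be a subset of members")
        for name, t in (("r_seed", self.r_seed), ("r_expand", self.r_expand)):
            if not (0 < t <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {t}")
        if self.r_expand > self.r_seed:
            raise ValueError("r_expand must not exceed r_seed")

    @property
    def size(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "is_seed": g in self.seed_genes,
                "mean_r_to_seeds": self.mean_r_to_seeds.get(g, np.nan),
            }
            for g in sorted(
                self.members,
                key=lambda g: (-self.mean_r_to_seeds.get(g, np.inf), g),
            )
        ]
        return pd.DataFrame(rows)


def pairwise_correlation(
    fc: FoldChangeMatrix,
    genes: Sequence[str] | None = None,
    cells: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """All-against-all Pearson correlation of gene fold-change vectors."""
    genes = list(genes) if genes is not None else fc.gene_ids
    cells = list(cells) if cells is not None else fc.sample_ids
    if len(cells) < 3:
        raise ValueError(f"need at least 3 cells, got {len(cells)}")
    x = fc.values.loc[genes, cells].to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = [genes[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes, r)


def find_seed_groups(
    c: CorrelationMatrix, r_seed: float = 0.9, min_size: int = 5
) -> list[set[str]]:
    """Connected components of the r >= ``r_seed`` graph with >= ``min_size`` genes.

    Components are returned largest first; ties are broken by the
    lexicographically smallest member id.  The union of the returned
    sets is the seed set for module expansion.
    """
    n = len(c.gene_ids)
    adj = c.values >= r_seed
    np.fill_diagonal(adj, False)
    graph = csr_matrix(adj)
    n_comp, labels = connected_components(graph, directed=False)
    groups: list[set[str]] = []
    for k in range(n_comp):
        idx = np.flatnonzero(labels == k)
        if len(idx) >= min_size:
            groups.append({c.gene_ids[i] for i in idx})
    groups.sort(key=lambda g: (-len(g), min(g)))
    return groups


def expand_module(
    seeds: set[str],
    c: CorrelationMatrix,
    r_expand: float = 0.75,
    r_seed: float = 0.9,
    min_seed_group: int = 5,
    rule: str = "mean",
) -> GeneModule:
    """Grow the seed set with genes correlated with it at >= ``r_expand``.

    ``rule`` selects how a candidate's correlation to the seed set is
    aggregated: ``"mean"`` (default), ``"min"`` (correlated with every
    seed), or ``"any"`` (correlated with at least one seed).
    """
    if not seeds:
        raise ValueError("seed set is empty")
    seed_list = sorted(seeds)
    seed_idx = c.index_of(seed_list)
    r_to_seeds = c.values[:, seed_idx]
    if rule == "mean":
        score = r_to_seeds.mean(axis=1)
    elif rule == "min":
        score = r_to_seeds.min(axis=1)
    elif rule == "any":
        score = r_to_seeds.max(axis=1)
    else:
        raise ValueError(f"unknown expansion rule {rule!r}")
    mean_score = r_to_seeds.mean(axis=1)
    members = set(seed_list) | {
        g for g, s in zip(c.gene_ids, score) if s >= r_expand
    }
    mean_r = {
        g: float(m) for g, m in zip(c.gene_ids, mean_score) if g in members
    }
    return GeneModule(
        seed_genes=set(seed_list),
        members=members,
        r_seed=r_seed,
        r_expand=r_expand,
        min_seed_group=min_seed_group,
        mean_r_to_seeds=mean_r,
    )


def mean_within_module_r(c: CorrelationMatrix, members: set[str]) -> float:
    """Mean off-diagonal pairwise correlation within a gene set."""
    idx = c.index_of(sorted(members))
    if len(idx) < 2:
        return float("nan")
    sub = c.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def threshold_sweep(
    c: CorrelationMatrix,
    seeds: set[str],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Module size and coherence as a function of the expansion threshold."""
    rows = []
    for t in thresholds:
        mod = expand_module(seeds, c, r_expand=t, r_seed=max(t, 0.9))
        rows.append(
            {
                "threshold": t,
                "module_size": mod.size,
                "mean_within_r": mean_within_module_r(c, mod.members),
            }
        )
    return pd.DataFrame(rows)
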
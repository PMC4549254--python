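"""Upstream-regulator prioritisation and cell-cycle stage annotation.

Candidate transcription factors are first required to have a predicted
binding site (within 5 kb upstream) for at least half of the module
genes, then ranked by the mean Pearson correlation between the TF's own
expression profile and each module gene's profile — a coordinately
expressed module driven by one regulator should track that regulator's
expression.  Module genes are also mapped to cell-cycle stages
(G1/S/G2/M) from a gene -> stage table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import FoldChangeMatrix
from .module_discovery import GeneModule

CELL_CYCLE_STAGES = ("G1", "S", "G2", "M")


@dataclass
class TFBSTable:
    """Map TF id -> set of genes with a predicted upstream binding site."""

    targets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tf, genes in self.targets.items():
            if not tf or not tf.strip():
                raise ValueError("blank TF id")
            if not genes:
                raise ValueError(f"TF {tf!r} has an empty target set")

    @classmethod
    def read_tsv(cls, path) -> "TFBSTable":
        targets: dict[str, set[str]] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line == "tf_id\ttarget_gene_id":
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"line {ln}: expected 'tf_id<TAB>target_gene_id'")
                targets.setdefault(parts[0], set()).add(parts[1])
        return cls(targets)

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("tf_id\ttarget_gene_id\n")
            for tf in sorted(self.targets):
                for g in sorted(self.targets[tf]):
                    fh.write(f"{tf}\t{g}\n")


@dataclass
class CellCycleMap:
    """Map gene id -> single cell-cycle stage."""

    stages: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, s in self.stages.items():
            if s not in CELL_CYCLE_STAGES:
                raise ValueError(f"unknown stage {s!r} for gene {g!r}")

    @classmethod
    def read_tsv(cls, path) -> "CellCycleMap":
        stages: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line == "gene_id\tstage":
                    continue
                g, s = line.split("\t")
                if g in stages and stages[g] != s:
                    raise ValueError(f"gene {g!r} mapped to two stages")
                stages[g] = s
        return cls(stages)


def common_tfs(
    t: TFBSTable, module: GeneModule, coverage: float = 0.5
) -> list[tuple[str, int]]:
    """TFs with binding sites upstream of at least ``coverage`` of the module.

    The count cutoff is ``ceil(coverage * |module|)`` so that 50% of a
    64-gene module means >= 32 genes.  Sorted by covered count
    descending, ties broken lexicographically by TF id.
    """
    if not module.members:
        raise ValueError("empty module")
    need = math.ceil(coverage * len(module.members))
    hits = []
    for tf, targets in t.targets.items():
        n = len(targets & module.members)
        if n >= need:
            hits.append((tf, n))
    hits.sort(key=lambda x: (-x[1], x[0]))
    return hits


def rank_tfs_by_correlation(
    tfs: Sequence[str],
    expr: FoldChangeMatrix,
    module: GeneModule,
    method: str = "per_gene",
    fallback_expr: FoldChangeMatrix | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Rank candidate TFs by correlation with module expression.

    ``method='per_gene'`` scores each TF by the mean, over module genes,
    of the Pearson correlation between the TF's profile and that gene's
    profile; ``method='module_mean'`` correlates the TF profile with the
    module's mean fold-change profile instead.  A TF without an
    expression row is looked up in ``fallback_expr`` (e.g. the
    pre-cleaning floored matrix) and flagged; if absent there too it is
    skipped and reported in the second return value.
    """
    module_genes = sorted(g for g in module.members if g in set(expr.gene_ids))
    if not module_genes:
        raise ValueError("no module genes present in the expression matrix")
    mod = expr.values.loc[module_genes].to_numpy(dtype=float)
    rows = []
    skipped: list[str] = []
    for tf in tfs:
        from_fallback = False
        if tf in expr.values.index:
            prof = expr.values.loc[tf].to_numpy(dtype=float)
        elif fallback_expr is not None and tf in fallback_expr.values.index:
            prof = fallback_expr.values.loc[tf, expr.sample_ids].to_numpy(dtype=float)
            from_fallback = True
        else:
            skipped.append(tf)
            continue
        if prof.std() == 0:
            skipped.append(tf)
            continue
        if method == "per_gene":
            rs = []
            for row in mod:
                if row.std() == 0:
                    continue
                rs.append(np.corrcoef(prof, row)[0, 1])
            score = float(np.mean(rs)) if rs else float("nan")
        elif method == "module_mean":
            mean_prof = mod.mean(axis=0)
            score = float(np.corrcoef(prof, mean_prof)[0, 1])
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"tf_id": tf, "mean_r": score, "from_fallback": from_fallback})
    out = pd.DataFrame(rows, columns=["tf_id", "mean_r", "from_fallback"])
    out = out.sort_values(
        ["mean_r", "tf_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out, skipped


def map_cell_cycle_stages(
    module: GeneModule, m: CellCycleMap
) -> tuple[dict[str, int], dict[str, str]]:
    """Partition module genes by cell-cycle stage.

    Returns the stage histogram (including ``unassigned``) and the
    per-gene assignment; histogram counts always sum to the module size.
    """
    assignment = {
        g: m.stages.get(g, "unassigned") for g in sorted(module.members)
    }
    hist = {s: 0 for s in (*CELL_CYCLE_STAGES, "unassigned")}
    for s in assignment.values():
        hist[s] += 1
    return hist, assignment
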
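"""Gene filters removing xenograft/culture artifacts and uninformative genes.

Single-cell matrices derived from a patient-derived-xenograft culture
carry two kinds of nuisance genes: (i) genes whose expression was
shifted by the engraftment or culture procedure rather than by the
tumor itself, detected as large fold-changes between the bulk profiles
(primary tumor pT, xenograft tumor xenoT, pooled single-cell bulkT);
and (ii) genes whose apparent gene-gene correlation is an artifact of
a trivially simple expression pattern — expressed in only one or two
cells, or near-constant ("housekeeping") across every cell.  Each
filter is a pure predicate on the gene's own values, so the filters
commute; every stage emits a :class:`FilterReport` for audit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import DEFAULT_FLOOR, ExpressionMatrix, FoldChangeMatrix


@dataclass
class FilterReport:
    """Audit record of one filtering stage."""

    stage: str
    genes_in: int
    genes_removed: set[str]
    genes_out: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genes_out != self.genes_in - len(self.genes_removed):
            raise ValueError(
                f"{self.stage}: genes_out {self.genes_out} != genes_in "
                f"{self.genes_in} - removed {len(self.genes_removed)}"
            )

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "genes_in": self.genes_in,
            "genes_out": self.genes_out,
            "n_removed": len(self.genes_removed),
            "thresholds": self.thresholds,
            "genes_removed": sorted(self.genes_removed),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def drop_all_zero_genes(
    m: ExpressionMatrix, cells: Sequence[str] | None = None
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove genes with FPKM 0 in every one of the given cells.

    A gene survives if any cell shows a strictly positive value, however
    small.
    """
    if cells is None:
        cells = m.sample_ids
    cells = list(cells)
    if not cells:
        raise ValueError("cell subset is empty")
    sub = m.values[cells].to_numpy(dtype=float)
    keep = (sub > 0).any(axis=1)
    if not keep.any():
        raise ValueError("all genes are zero across the given cells")
    kept_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    removed = {g for g, k in zip(m.gene_ids, keep) if not k}
    report = FilterReport(
        stage="drop_all_zero",
        genes_in=len(m.gene_ids),
        genes_removed=removed,
        genes_out=len(kept_ids),
        thresholds={},
    )
    return m.subset_genes(kept_ids), report


def xenograft_deg_filter(
    pT: pd.Series,
    xenoT: pd.Series,
    bulkT: pd.Series,
    threshold: float = 2.0,
    floor: float = DEFAULT_FLOOR,
) -> tuple[set[str], FilterReport]:
    """Genes differentially expressed in any bulk-profile comparison.

    A gene is flagged when |log2(a/b)| exceeds ``threshold`` in any of
    the ordered pairs (pT, xenoT), (xenoT, bulkT), (pT, bulkT): such a
    shift reflects the xenografting or culture procedure, not the tumor.
    Both directions count — either one marks a procedure-induced change.
    Zeros are guarded up to ``floor`` before the ratio.
    """
    universe = list(pT.index)
    for name, prof in (("xenoT", xenoT), ("bulkT", bulkT)):
        if list(prof.index) != universe:
            raise ValueError(f"gene universe of {name} does not match pT")
    a = np.maximum(pT.to_numpy(dtype=float), floor)
    b = np.maximum(xenoT.to_numpy(dtype=float), floor)
    c = np.maximum(bulkT.to_numpy(dtype=float), floor)
    flagged = np.zeros(len(universe), dtype=bool)
    for x, y in ((a, b), (b, c), (a, c)):
        flagged |= np.abs(np.log2(x / y)) > threshold
    removed = {g for g, f in zip(universe, flagged) if f}
    report = FilterReport(
        stage="xenograft_deg",
        genes_in=len(universe),
        genes_removed=removed,
        genes_out=len(universe) - len(removed),
        thresholds={"log2_fc": threshold, "floor": floor},
    )
    return removed, report


def simple_pattern_filter(
    m: ExpressionMatrix,
    cells: Sequence[str] | None = None,
    expressed_above: float = DEFAULT_FLOOR,
    max_expressing_cells: int = 2,
) -> tuple[set[str], FilterReport]:
    """Genes expressed in at most ``max_expressing_cells`` cells.

    Such genes produce spuriously high gene-gene correlations driven by
    a shared near-zero baseline; "expressed" means FPKM above the floor.
    """
    if cells is None:
        cells = m.sample_ids
    cells = list(cells)
    if max_expressing_cells >= len(cells):
        raise ValueError(
            f"max_expressing_cells ({max_expressing_cells}) must be below "
            f"the number of cells ({len(cells)})"
        )
    sub = m.values[cells].to_numpy(dtype=float)
    n_expr = (sub > expressed_above).sum(axis=1)
    removed = {g for g, n in zip(m.gene_ids, n_expr) if n <= max_expressing_cells}
    report = FilterReport(
        stage="simple_pattern",
        genes_in=len(m.gene_ids),
        genes_removed=removed,
        genes_out=len(m.gene_ids) - len(removed),
        thresholds={
            "expressed_above": expressed_above,
            "max_expressing_cells": max_expressing_cells,
        },
    )
    return removed, report


def ubiquitous_filter(
    fc: FoldChangeMatrix,
    cells: Sequence[str] | None = None,
    bound: float = 3.0,
) -> tuple[set[str], FilterReport]:
    """Genes expressed in every cell with log2 fold-change inside (-bound, bound).

    These near-constant housekeeping-like genes correlate with each
    other trivially and carry no subgroup signal.  The interval is open:
    a gene touching the bound in any cell is retained.
    """
    if cells is None:
        cells = fc.sample_ids
    cells = list(cells)
    vals = fc.values[cells].to_numpy(dtype=float)
    expr = fc.expressed[cells].to_numpy(dtype=bool)
    everywhere = expr.all(axis=1)
    within = (np.abs(vals) < bound).all(axis=1)
    removed = {
        g for g, e, w in zip(fc.gene_ids, everywhere, within) if e and w
    }
    report = FilterReport(
        stage="ubiquitous",
        genes_in=len(fc.gene_ids),
        genes_removed=removed,
        genes_out=len(fc.gene_ids) - len(removed),
        thresholds={"log2_fc_bound": bound},
    )
    return removed, report


def sample_correlation_report(
    profiles: Mapping[str, pd.Series],
    before: ExpressionMatrix,
    after: ExpressionMatrix,
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Pairwise Pearson r between bulk profiles, before vs after cleaning.

    Correlations are computed on log2 of floored FPKM, restricted to the
    gene sets of the pre- and post-cleaning matrices respectively.
    """

    def _r(x: pd.Series, y: pd.Series, genes: list[str]) -> float:
        shared = [g for g in genes if g in x.index and g in y.index]
        if len(shared) < 3:
            raise ValueError(f"fewer than 3 shared genes ({len(shared)})")
        xv = np.log2(np.maximum(x.loc[shared].to_numpy(dtype=float), floor))
        yv = np.log2(np.maximum(y.loc[shared].to_numpy(dtype=float), floor))
        if xv.std() == 0 or yv.std() == 0:
            return math.nan
        return float(stats.pearsonr(xv, yv).statistic)

    roles = list(profiles)
    rows = []
    for i, ra in enumerate(roles):
        for rb in roles[i + 1:]:
            rows.append(
                {
                    "pair": f"{ra}~{rb}",
                    "r_before": _r(profiles[ra], profiles[rb], before.gene_ids),
                    "r_after": _r(profiles[ra], profiles[rb], after.gene_ids),
                }
            )
    return pd.DataFrame(rows)
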
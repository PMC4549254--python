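"""Expression matrix I/O, FPKM flooring and log2 fold-change computation.

The pipeline consumes gene x sample FPKM matrices stored as plain TSV
(first column ``gene_id``, one column per sample).  Sample roles
(single cell, matched normal, primary tumor, xenograft tumor, pooled
single-cell bulk, cohort sample) travel in an optional ``#role:``
comment line so the file body stays a standard numeric TSV.

FPKM values are relative abundances; the only normalisation applied
here is the small-value floor (values in ``(0, floor)`` are raised to
``floor``) and, downstream of it, the per-gene log2 fold-change over a
designated sample subset (each value divided by the gene's mean over
the subset, then log2-transformed).  Exact zeros are kept as zeros in
the stored matrix so that the all-zero gene filter still sees them;
only at fold-change time are they guarded up to the floor to avoid
minus infinity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_FLOOR = 0.1

VALID_ROLES = frozenset(
    {"single_cell", "mN", "pT", "xenoT", "bulkT", "cohort"}
)


class ExpressionError(ValueError):
    """Raised on malformed expression input (duplicates, negatives, ...)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ExpressionError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Non-negative FPKM values, genes in rows, samples in columns.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    roles
        Mapping sample id -> role; samples absent from the mapping
        default to ``single_cell``.
    """

    values: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ExpressionError(
                f"non-numeric value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ExpressionError(
                f"negative value {arr[g, s]} at gene "
                f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )
        roles = {s: self.roles.get(s, "single_cell") for s in self.values.columns}
        for s, r in roles.items():
            if r not in VALID_ROLES:
                raise ExpressionError(f"unknown role {r!r} for sample {s!r}")
        self.roles = roles

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.values.columns if self.roles[s] == role]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(self.values.loc[genes].copy(), dict(self.roles))


@dataclass
class FoldChangeMatrix:
    """Per-gene log2 fold-change of each sample over the gene's subset mean.

    ``expressed`` marks cells whose raw FPKM exceeded the floor (used by
    the ubiquitous-expression filter); ``mean_at_floor`` flags genes
    whose floored subset mean collapsed to the floor itself.
    """

    values: pd.DataFrame
    over: list[str]
    floor: float
    floored_mean: pd.Series
    expressed: pd.DataFrame
    mean_at_floor: set[str] = field(default_factory=set)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: Iterable[str]) -> "FoldChangeMatrix":
        genes = list(genes)
        return FoldChangeMatrix(
            values=self.values.loc[genes].copy(),
            over=list(self.over),
            floor=self.floor,
            floored_mean=self.floored_mean.loc[genes].copy(),
            expressed=self.expressed.loc[genes].copy(),
            mean_at_floor={g for g in self.mean_at_floor if g in set(genes)},
        )


# ---------------------------------------------------------------------------
# TSV reading / writing


def _fmt(x: float) -> str:
    # shortest float repr round-trips; integers keep a trailing ".0"
    return repr(float(x))


def _parse_role_line(line: str) -> dict[str, str]:
    body = line[len("#role:"):].strip()
    roles: dict[str, str] = {}
    if not body:
        return roles
    for pair in body.split("\t"):
        if "=" not in pair:
            raise ExpressionError(f"malformed role entry {pair!r}")
        s, r = pair.split("=", 1)
        roles[s] = r
    return roles


def read_fpkm_matrix(path, roles: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV into an :class:`ExpressionMatrix`.

    An optional leading ``#role:`` comment line carries sample roles as
    tab-separated ``sample=role`` pairs; ``roles`` passed by the caller
    override it.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    return _read_fpkm_text(text, roles)


def _read_fpkm_text(text: str, roles: Mapping[str, str] | None = None) -> ExpressionMatrix:
    lines = text.splitlines()
    file_roles: dict[str, str] = {}
    start = 0
    while start < len(lines) and lines[start].startswith("#"):
        if lines[start].startswith("#role:"):
            file_roles.update(_parse_role_line(lines[start]))
        start += 1
    if start >= len(lines):
        raise ExpressionError("empty expression TSV")
    header = lines[start].split("\t")
    if header[0] != "gene_id":
        raise ExpressionError("first header column must be 'gene_id'")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[start + 1:], start=start + 2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != len(sample_ids) + 1:
            raise ExpressionError(f"line {ln}: expected {len(sample_ids) + 1} fields")
        gene_ids.append(parts[0])
        row = []
        for j, cell in enumerate(parts[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise ExpressionError(
                    f"non-numeric cell {cell!r} at gene {parts[0]!r}, "
                    f"sample {sample_ids[j]!r} (line {ln})"
                ) from None
            if v < 0:
                raise ExpressionError(
                    f"negative value {cell} at gene {parts[0]!r}, "
                    f"sample {sample_ids[j]!r} (line {ln})"
                )
            row.append(v)
        rows.append(row)
    _check_unique(gene_ids, "gene")
    df = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    merged = dict(file_roles)
    if roles:
        merged.update(roles)
    return ExpressionMatrix(df, merged)


def write_fpkm_matrix(m: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV with a ``#role:`` header line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(fpkm_matrix_to_text(m))


def fpkm_matrix_to_text(m: ExpressionMatrix) -> str:
    buf = io.StringIO()
    role_pairs = "\t".join(f"{s}={m.roles[s]}" for s in m.sample_ids)
    buf.write(f"#role: {role_pairs}\n")
    buf.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
    arr = m.values.to_numpy(dtype=float)
    for g, gid in enumerate(m.gene_ids):
        buf.write(gid + "\t" + "\t".join(_fmt(v) for v in arr[g]) + "\n")
    return buf.getvalue()


def write_fold_change_matrix(fc: FoldChangeMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(fc.sample_ids) + "\n")
        arr = fc.values.to_numpy(dtype=float)
        for g, gid in enumerate(fc.gene_ids):
            fh.write(gid + "\t" + "\t".join(_fmt(v) for v in arr[g]) + "\n")


# ---------------------------------------------------------------------------
# Floor and fold-change


def floor_fpkm(m: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Raise values in ``(0, floor)`` to ``floor``; zeros stay zero.

    Idempotent; values at or above the floor are untouched.
    """
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    arr = m.values.to_numpy(dtype=float).copy()
    mask = (arr > 0) & (arr < floor)
    arr[mask] = floor
    return ExpressionMatrix(
        pd.DataFrame(arr, index=m.values.index, columns=m.values.columns),
        dict(m.roles),
    )


def log2_fold_change(
    m: ExpressionMatrix,
    over: Sequence[str] | None = None,
    floor: float = DEFAULT_FLOOR,
) -> FoldChangeMatrix:
    """Per-gene log2 ratio of each sample to the gene's mean over ``over``.

    Exact zeros are guarded up to ``floor`` before the ratio so that
    genes expressed in a strict subset of samples do not produce minus
    infinity.  Genes with no positive value across ``over`` must be
    removed beforehand (see ``cleaning.drop_all_zero_genes``).
    """
    if over is None:
        over = m.sample_ids
    over = list(over)
    if not over:
        raise ValueError("'over' sample subset is empty")
    missing = [s for s in over if s not in set(m.sample_ids)]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    raw = m.values.to_numpy(dtype=float)
    sub = m.values[over].to_numpy(dtype=float)
    all_zero = (sub <= 0).all(axis=1)
    if all_zero.any():
        bad = [m.gene_ids[i] for i in np.flatnonzero(all_zero)]
        raise ValueError(
            f"{len(bad)} gene(s) with no positive value across the subset "
            f"(first: {bad[:5]}); drop all-zero genes first"
        )
    guarded = np.maximum(raw, floor)
    guarded_sub = np.maximum(sub, floor)
    mean = guarded_sub.mean(axis=1)
    fc = np.log2(guarded / mean[:, None])
    mean_at_floor = {
        m.gene_ids[i]
        for i in np.flatnonzero(np.isclose(mean, floor, rtol=0, atol=1e-12))
    }
    return FoldChangeMatrix(
        values=pd.DataFrame(fc, index=m.values.index, columns=m.values.columns),
        over=over,
        floor=floor,
        floored_mean=pd.Series(mean, index=m.values.index),
        expressed=m.values > floor,
        mean_at_floor=mean_at_floor,
    )
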
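"""Synthetic data with planted structure for end-to-end pipeline validation.

Generates every input the pipeline consumes — a single-cell FPKM matrix
with a planted co-expressed module driven by a binary latent cell
state, the bulk profile quartet with planted procedure-induced DEGs, a
clinical cohort whose hazard depends on the latent state, and a
TF-target table with one planted regulator among decoys — together
with the ground truth needed to score recovery.

Model choices (see docs/methods.md for rationale):

* Baseline FPKM is log-normal per gene with log-normal per-cell
  biological noise; the pipeline consumes FPKM, not counts, so no
  count model is used.
* The module effect is symmetric in log space: module genes are
  multiplied by ``2**effect`` in latent-up cells and by ``2**-effect``
  in latent-down cells, mirroring cell-cycle genes that are abundant in
  cycling cells and essentially silent otherwise.  At effect 0 module
  genes are distributionally identical to background.
* Dropout is Bernoulli per gene-cell with an expression-dependent
  probability (logistic in log expression, sharp), calibrated so the
  matrix-wide expected dropout rate equals ``dropout_prob``.  This
  concentrates zeros in weakly expressed transcripts, the regime where
  capture failure actually occurs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .tf_cellcycle import TFBSTable


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the 34-cell study regime."""

    n_cells: int = 34
    n_genes: int = 2000
    module_size: int = 30
    latent_up_fraction: float = 13 / 34
    effect_size: float = 3.0  # log2 units
    baseline_mu: float = 1.0  # ln-scale FPKM mean
    baseline_sigma: float = 1.0  # ln-scale FPKM sd
    cell_noise_sd: float = 0.6  # ln-scale per-cell biological noise
    dropout_prob: float = 0.2
    dropout_sharpness: float = 0.25  # ln-units; logistic width of dropout curve
    n_simple_genes: int = 100
    n_housekeeping_genes: int = 100
    n_artifact_degs: int = 150
    artifact_log2_shift: float = 3.0
    bulk_noise_sd: float = 0.15  # ln-scale
    n_decoy_tfs: int = 10
    regulator_noise_sd: float = 0.4  # ln-scale, extra noise on the planted TF
    tf_target_fraction: float = 0.8
    cohort_n: int = 400
    true_hr: float = 2.0
    censor_rate: float = 0.3
    baseline_median_survival_days: float = 730.0
    covariate_assoc: float = 0.8  # log-odds shift of covariates with latent state

    def __post_init__(self) -> None:
        reserved = (
            self.module_size
            + self.n_simple_genes
            + self.n_housekeeping_genes
            + 1
            + self.n_decoy_tfs
            + self.n_artifact_degs
        )
        if reserved >= self.n_genes:
            raise ValueError(
                f"n_genes ({self.n_genes}) too small for the planted gene classes "
                f"({reserved})"
            )
        for name in ("latent_up_fraction", "dropout_prob", "censor_rate",
                     "tf_target_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("effect_size", "artifact_log2_shift", "true_hr"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery."""

    latent_up_cells: list[str]
    module_genes: list[str]
    simple_genes: list[str]
    housekeeping_genes: list[str]
    regulator_gene: str
    decoy_tfs: list[str]
    artifact_genes: list[str] = field(default_factory=list)
    cohort_latent_up: list[str] = field(default_factory=list)
    true_hr: float = 1.0

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _layout(cfg: SyntheticConfig) -> dict[str, list[str]]:
    """Deterministic assignment of gene ids to planted classes."""
    ids = _gene_ids(cfg.n_genes)
    i = 0
    module = ids[i:i + cfg.module_size]; i += cfg.module_size
    simple = ids[i:i + cfg.n_simple_genes]; i += cfg.n_simple_genes
    hk = ids[i:i + cfg.n_housekeeping_genes]; i += cfg.n_housekeeping_genes
    regulator = ids[i]; i += 1
    decoys = ids[i:i + cfg.n_decoy_tfs]; i += cfg.n_decoy_tfs
    artifacts = ids[i:i + cfg.n_artifact_degs]; i += cfg.n_artifact_degs
    background = ids[i:]
    return {
        "all": ids,
        "module": module,
        "simple": simple,
        "housekeeping": hk,
        "regulator": [regulator],
        "decoys": decoys,
        "artifacts": artifacts,
        "background": background,
    }


def _dropout_mask(
    rng: np.random.Generator,
    values: np.ndarray,
    rate: float,
    tau: float,
) -> np.ndarray:
    """Expression-dependent Bernoulli dropout with calibrated marginal rate.

    Per-entry probability is ``sigmoid(-(ln v - x0)/tau)``; the midpoint
    ``x0`` is solved by bisection so the expected fraction of dropped
    entries equals ``rate``.
    """
    if rate <= 0:
        return np.zeros_like(values, dtype=bool)
    ln_v = np.log(np.maximum(values, 1e-300))

    def mean_p(x0: float) -> float:
        return float((1.0 / (1.0 + np.exp((ln_v - x0) / tau))).mean())

    lo, hi = ln_v.min() - 10.0, ln_v.max() + 10.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if mean_p(mid) < rate:
            lo = mid
        else:
            hi = mid
    x0 = (lo + hi) / 2.0
    p = 1.0 / (1.0 + np.exp((ln_v - x0) / tau))
    return rng.random(values.shape) < p


def _latent_states(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    n_up = int(round(frac * n))
    states = np.zeros(n, dtype=bool)
    states[rng.choice(n, size=n_up, replace=False)] = True
    return states


def generate_single_cell_dataset(
    cfg: SyntheticConfig, seed: int
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Single-cell FPKM matrix with a planted module and latent cell state."""
    rng = np.random.default_rng(seed)
    lay = _layout(cfg)
    ids = lay["all"]
    cells = [f"C{i + 1:02d}" for i in range(cfg.n_cells)]
    up = _latent_states(rng, cfg.n_cells, cfg.latent_up_fraction)

    base = np.exp(rng.normal(cfg.baseline_mu, cfg.baseline_sigma, cfg.n_genes))
    vals = base[:, None] * np.exp(
        rng.normal(0.0, cfg.cell_noise_sd, (cfg.n_genes, cfg.n_cells))
    )

    pos = {g: i for i, g in enumerate(ids)}
    state_sign = np.where(up, 1.0, -1.0)

    mod_idx = np.array([pos[g] for g in lay["module"]])
    vals[mod_idx] *= 2.0 ** (cfg.effect_size * state_sign)[None, :]

    reg_idx = pos[lay["regulator"][0]]
    vals[reg_idx] = (
        base[reg_idx]
        * 2.0 ** (cfg.effect_size * state_sign)
        * np.exp(rng.normal(0.0, cfg.regulator_noise_sd, cfg.n_cells))
    )

    hk_idx = np.array([pos[g] for g in lay["housekeeping"]])
    hk_base = 0.5 + np.exp(rng.normal(2.0, 0.5, len(hk_idx)))
    vals[hk_idx] = hk_base[:, None] * (
        1.0 + rng.normal(0.0, 0.05, (len(hk_idx), cfg.n_cells))
    )

    drop = _dropout_mask(rng, vals, cfg.dropout_prob, cfg.dropout_sharpness)
    vals = np.where(drop, 0.0, vals)

    smp_idx = np.array([pos[g] for g in lay["simple"]])
    vals[smp_idx] = 0.0
    for i in smp_idx:
        k = int(rng.integers(1, 3))
        which = rng.choice(cfg.n_cells, size=k, replace=False)
        vals[i, which] = np.exp(rng.normal(2.0, 1.0, k))

    m = ExpressionMatrix(
        pd.DataFrame(vals, index=ids, columns=cells),
        {c: "single_cell" for c in cells},
    )
    truth = GroundTruth(
        latent_up_cells=[c for c, u in zip(cells, up) if u],
        module_genes=list(lay["module"]),
        simple_genes=list(lay["simple"]),
        housekeeping_genes=list(lay["housekeeping"]),
        regulator_gene=lay["regulator"][0],
        decoy_tfs=list(lay["decoys"]),
        artifact_genes=list(lay["artifacts"]),
        true_hr=cfg.true_hr,
    )
    return m, truth


def generate_bulk_quartet(
    cfg: SyntheticConfig, seed: int
) -> tuple[dict[str, pd.Series], list[str]]:
    """Bulk profiles mN / pT / xenoT / bulkT with planted procedure DEGs.

    ``pT`` is the row mean of a pre-dropout single-cell draw; ``xenoT``
    and ``bulkT`` add log-normal measurement noise plus exact
    ``2**(+-artifact_log2_shift)`` multipliers on the planted artifact
    genes (xenografting artifacts enter at xenoT and persist in bulkT;
    culture artifacts enter at bulkT only), so every planted gene
    exceeds the DEG threshold by construction.  ``mN`` suppresses the
    planted tumor module.
    """
    rng = np.random.default_rng(seed)
    lay = _layout(cfg)
    ids = lay["all"]
    pos = {g: i for i, g in enumerate(ids)}
    up = _latent_states(rng, cfg.n_cells, cfg.latent_up_fraction)
    base = np.exp(rng.normal(cfg.baseline_mu, cfg.baseline_sigma, cfg.n_genes))
    vals = base[:, None] * np.exp(
        rng.normal(0.0, cfg.cell_noise_sd, (cfg.n_genes, cfg.n_cells))
    )
    sign = np.where(up, 1.0, -1.0)
    mod_idx = np.array([pos[g] for g in lay["module"]])
    vals[mod_idx] *= 2.0 ** (cfg.effect_size * sign)[None, :]
    pT = vals.mean(axis=1)

    noise = lambda: np.exp(rng.normal(0.0, cfg.bulk_noise_sd, cfg.n_genes))
    art = lay["artifacts"]
    half = len(art) // 2
    xeno_art = np.array([pos[g] for g in art[:half]], dtype=int)
    cult_art = np.array([pos[g] for g in art[half:]], dtype=int)
    art_sign = rng.choice([-1.0, 1.0], size=cfg.n_artifact_degs)
    # a down-shift on a near-floor gene would be erased by the FPKM floor;
    # force such artifacts upward so every planted DEG exceeds the threshold
    art_idx_all = np.concatenate([xeno_art, cult_art]).astype(int)
    low = pT[art_idx_all] < 0.1 * 2.0**cfg.artifact_log2_shift
    art_sign[low] = 1.0

    xenoT = pT * noise()
    if len(xeno_art):
        xenoT[xeno_art] = pT[xeno_art] * 2.0 ** (
            cfg.artifact_log2_shift * art_sign[:half]
        )
    bulkT = xenoT * noise()
    if len(cult_art):
        bulkT[cult_art] = xenoT[cult_art] * 2.0 ** (
            cfg.artifact_log2_shift * art_sign[half:]
        )
    mN = pT * noise()
    mN[mod_idx] = pT[mod_idx] * 2.0 ** (-cfg.effect_size)

    profiles = {
        "mN": pd.Series(mN, index=ids),
        "pT": pd.Series(pT, index=ids),
        "xenoT": pd.Series(xenoT, index=ids),
        "bulkT": pd.Series(bulkT, index=ids),
    }
    return profiles, list(art)


def generate_clinical_cohort(
    cfg: SyntheticConfig, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Cohort expression matrix plus clinical table with latent-state hazard.

    Survival times are exponential with hazard multiplied by ``true_hr``
    for latent-up samples; censoring is an independent exponential
    calibrated to the configured overall censoring fraction.  Covariates
    (age, stage, gender, smoking-cessation years) are partially
    associated with the latent state at strength ``covariate_assoc``.
    """
    rng = np.random.default_rng(seed)
    lay = _layout(cfg)
    ids = lay["all"]
    pos = {g: i for i, g in enumerate(ids)}
    n = cfg.cohort_n
    samples = [f"S{i + 1:04d}" for i in range(n)]
    up = _latent_states(rng, n, cfg.latent_up_fraction)

    base = np.exp(rng.normal(cfg.baseline_mu, cfg.baseline_sigma, cfg.n_genes))
    vals = base[:, None] * np.exp(
        rng.normal(0.0, cfg.cell_noise_sd, (cfg.n_genes, n))
    )
    sign = np.where(up, 1.0, -1.0)
    mod_idx = np.array([pos[g] for g in lay["module"]])
    vals[mod_idx] *= 2.0 ** (cfg.effect_size * sign)[None, :]
    reg_idx = pos[lay["regulator"][0]]
    vals[reg_idx] = (
        base[reg_idx]
        * 2.0 ** (cfg.effect_size * sign)
        * np.exp(rng.normal(0.0, cfg.regulator_noise_sd, n))
    )
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=ids, columns=samples),
        {s: "cohort" for s in samples},
    )

    lam0 = np.log(2.0) / cfg.baseline_median_survival_days
    lam = lam0 * np.where(up, cfg.true_hr, 1.0)
    t_event = rng.exponential(1.0 / lam)
    mean_lam = lam0 * (1 + (cfg.true_hr - 1) * cfg.latent_up_fraction)
    if cfg.censor_rate > 0:
        lam_c = mean_lam * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    def assoc_bernoulli(p0: float) -> np.ndarray:
        logit = np.log(p0 / (1 - p0)) + cfg.covariate_assoc * np.where(up, 1.0, 0.0)
        return (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    age = np.clip(rng.normal(65.0, 10.0, n) - 2.0 * np.where(up, 1.0, 0.0), 30, 95)
    stage34 = assoc_bernoulli(0.18)
    male = assoc_bernoulli(0.45)
    reformed_lt15 = assoc_bernoulli(0.45)
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "time": np.round(time, 1),
            "event": event,
            "age": np.round(age, 1),
            "gender": np.where(male == 1, "male", "female"),
            "stage": np.where(stage34 == 1, rng.choice([3, 4], n), rng.choice([1, 2], n)),
            "tobacco_reformed_years": np.where(
                reformed_lt15 == 1, rng.uniform(0, 15, n), rng.uniform(15, 40, n)
            ).round(1),
        }
    )
    truth = GroundTruth(
        latent_up_cells=[],
        module_genes=list(lay["module"]),
        simple_genes=list(lay["simple"]),
        housekeeping_genes=list(lay["housekeeping"]),
        regulator_gene=lay["regulator"][0],
        decoy_tfs=list(lay["decoys"]),
        cohort_latent_up=[s for s, u in zip(samples, up) if u],
        true_hr=cfg.true_hr,
    )
    return expr, clinical, truth


def generate_tfbs_table(cfg: SyntheticConfig, seed: int) -> TFBSTable:
    """TF-target table: planted regulator covers most of the module.

    The regulator targets a fixed fraction of module genes plus random
    background genes; each decoy TF targets a random gene set of the
    same total size.
    """
    rng = np.random.default_rng(seed)
    lay = _layout(cfg)
    module = lay["module"]
    n_mod_targets = int(np.ceil(cfg.tf_target_fraction * len(module)))
    mod_targets = list(
        np.array(module)[rng.choice(len(module), n_mod_targets, replace=False)]
    )
    n_bg = max(n_mod_targets // 4, 1)
    bg_pool = lay["background"]
    bg_targets = list(
        np.array(bg_pool)[rng.choice(len(bg_pool), n_bg, replace=False)]
    )
    targets = {lay["regulator"][0]: set(mod_targets) | set(bg_targets)}
    total = n_mod_targets + n_bg
    all_ids = lay["all"]
    for tf in lay["decoys"]:
        targets[tf] = set(
            np.array(all_ids)[rng.choice(len(all_ids), total, replace=False)]
        ) - {tf}
    return TFBSTable(targets)


def generate_cell_cycle_map(
    cfg: SyntheticConfig, seed: int, module_fraction: float = 0.6
):
    """Gene -> stage table covering part of the module plus background."""
    from .tf_cellcycle import CELL_CYCLE_STAGES, CellCycleMap

    rng = np.random.default_rng(seed)
    lay = _layout(cfg)
    module = lay["module"]
    n_mod = int(round(module_fraction * len(module)))
    chosen = list(np.array(module)[rng.choice(len(module), n_mod, replace=False)])
    bg = list(
        np.array(lay["background"])[
            rng.choice(len(lay["background"]), 50, replace=False)
        ]
    )
    stages = {
        g: CELL_CYCLE_STAGES[rng.integers(0, 4)] for g in chosen + bg
    }
    return CellCycleMap(stages)


def write_bundle(cfg: SyntheticConfig, seed: int, outdir) -> dict[str, str]:
    """Emit the full synthetic input bundle as TSV/CSV plus ground truth."""
    from .expression_io import write_fpkm_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells, truth = generate_single_cell_dataset(cfg, seed)
    profiles, artifacts = generate_bulk_quartet(cfg, seed + 1)
    cohort, clinical, cohort_truth = generate_clinical_cohort(cfg, seed + 2)
    tfbs = generate_tfbs_table(cfg, seed + 3)
    truth.artifact_genes = artifacts
    truth.cohort_latent_up = cohort_truth.cohort_latent_up

    paths = {}
    write_fpkm_matrix(cells, outdir / "single_cells.tsv")
    paths["single_cells"] = str(outdir / "single_cells.tsv")
    quartet = ExpressionMatrix(
        pd.DataFrame({r: profiles[r] for r in ("mN", "pT", "xenoT", "bulkT")}),
        {r: r for r in ("mN", "pT", "xenoT", "bulkT")},
    )
    write_fpkm_matrix(quartet, outdir / "bulk_quartet.tsv")
    paths["bulk_quartet"] = str(outdir / "bulk_quartet.tsv")
    write_fpkm_matrix(cohort, outdir / "cohort.tsv")
    paths["cohort"] = str(outdir / "cohort.tsv")
    clinical.to_csv(outdir / "clinical.csv", index=False)
    paths["clinical"] = str(outdir / "clinical.csv")
    tfbs.write_tsv(outdir / "tfbs.tsv")
    paths["tfbs"] = str(outdir / "tfbs.tsv")
    ccm = generate_cell_cycle_map(cfg, seed + 4)
    with open(outdir / "cell_cycle.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_id\tstage\n")
        for g in sorted(ccm.stages):
            fh.write(f"{g}\t{ccm.stages[g]}\n")
    paths["cell_cycle"] = str(outdir / "cell_cycle.tsv")
    truth.to_json(outdir / "ground_truth.json")
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
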
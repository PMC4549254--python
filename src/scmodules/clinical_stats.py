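"""Association of module subgroups with clinical variables and survival.

Implements the clinical side of the analysis: 2x2 contingency tables of
subgroup (down/up) against dichotomised clinical variables, Pearson
chi-square tests and cross-product odds ratios with log-scale Wald
confidence intervals, multivariate logistic regression, Kaplan-Meier
curves, the two-group log-rank test, Cox proportional-hazards fits, and
a per-gene survival screen over module genes.

Conventions: the ``up`` subgroup is the index group throughout — odds
ratios and hazard ratios are reported for up versus down, so a value
above 1 means the index outcome (e.g. death) is enriched among
module-up samples.  The chi-square statistic is the uncorrected Pearson
statistic with 1 df (Yates continuity correction available via flag).
Survival machinery (product-limit curves, log-rank, Cox with Efron tie
handling) is backed by lifelines; logistic fits by statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .expression_io import FoldChangeMatrix
from .module_discovery import GeneModule
from .subgrouping import SubgroupAssignment

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

# Published multivariate-era clinical table for the 462-sample lung
# adenocarcinoma cohort split by module up/down regulation.  Each row is
# (down reference-level count, down index-level count,
#  up reference-level count, up index-level count); the index level is
# the one whose enrichment in the up group is reported as OR > 1.
LADC_CLINICAL_TABLE: dict[str, dict] = {
    "gender": {"levels": ("female", "male"), "counts": (140, 88, 112, 122)},
    "age": {"levels": (">=65", "<65"), "counts": (140, 81, 111, 111)},
    "stage": {"levels": ("1-2", "3-4"), "counts": (190, 37, 168, 66)},
    "tobacco_reformed": {"levels": (">=15y", "<15y"), "counts": (79, 64, 36, 91)},
    "survival": {"levels": ("alive", "death"), "counts": (188, 40, 159, 75)},
}


# Published subgroup assignment for the squamous (LUSC) cohort: 107 of
# 501 samples fell in the module-down group.
LUSC_GROUP_COUNTS = {"down": 107, "total": 501}


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE diverges, result withheld."""


@dataclass
class ContingencyTable2x2:
    """Counts (a, b) = down column, (c, d) = up column.

    ``a``/``c`` hold the reference clinical level, ``b``/``d`` the index
    level whose enrichment in the up group is being tested.
    """

    a: int
    b: int
    c: int
    d: int
    variable: str = ""
    n_missing: int = 0

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError(f"negative count in {counts}")
        if sum(counts) == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi_square: float
    p_value: float
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("odds ratio outside its confidence interval")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class SurvivalResult:
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    hazard_ratios: pd.DataFrame | None = None


def tabulate_2x2(
    labels: SubgroupAssignment | Mapping[str, str],
    variable: pd.Series,
    index_level,
    reference_level,
    name: str = "",
) -> ContingencyTable2x2:
    """Cross-tabulate subgroup labels against a dichotomous variable.

    ``variable`` is indexed by sample id; samples with a missing value
    are dropped and counted in ``n_missing``.  Values outside the two
    declared levels are rejected.
    """
    label_map = labels.label if isinstance(labels, SubgroupAssignment) else dict(labels)
    a = b = c = d = 0
    n_missing = 0
    n_used = 0
    for s, grp in label_map.items():
        v = variable.get(s, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_missing += 1
            continue
        if v == reference_level:
            idx = False
        elif v == index_level:
            idx = True
        else:
            raise ValueError(
                f"variable {name or variable.name!r} not dichotomous: "
                f"unexpected value {v!r} for sample {s!r}"
            )
        n_used += 1
        if grp == "down":
            b += idx
            a += not idx
        else:
            d += idx
            c += not idx
    if n_used == 0:
        raise ValueError("all samples missing the variable")
    return ContingencyTable2x2(
        a=a, b=b, c=c, d=d, variable=name or str(variable.name), n_missing=n_missing
    )


def percent_breakdown(t: ContingencyTable2x2) -> dict[str, float]:
    """Per-cell percentages of the column (group) totals, to 0.1."""
    down_total = t.a + t.b
    up_total = t.c + t.d
    if down_total == 0 or up_total == 0:
        raise ValueError("a group column is empty")
    return {
        "down_ref_pct": round(100.0 * t.a / down_total, 1),
        "down_index_pct": round(100.0 * t.b / down_total, 1),
        "up_ref_pct": round(100.0 * t.c / up_total, 1),
        "up_index_pct": round(100.0 * t.d / up_total, 1),
    }


def odds_ratio(t: ContingencyTable2x2, yates: bool = False) -> AssociationResult:
    """Cross-product odds ratio of the index outcome in up vs down.

    OR = (d*a)/(b*c); the 95% CI uses the log-OR normal approximation
    exp(ln OR +- 1.96*sqrt(1/a + 1/b + 1/c + 1/d)).  If any cell is
    zero, 0.5 is added to every cell (Haldane-Anscombe) and the result
    flagged.  The chi-square statistic is Pearson's on the original
    counts, uncorrected unless ``yates``.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    orr = (d * a) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(orr) - Z_95 * se)
    ci_high = math.exp(math.log(orr) + Z_95 * se)
    chi2, p = pearson_chi_square(t, yates=yates)
    return AssociationResult(
        odds_ratio=orr,
        ci_low=ci_low,
        ci_high=ci_high,
        chi_square=chi2,
        p_value=p,
        continuity_corrected=corrected,
    )


def pearson_chi_square(
    t: ContingencyTable2x2, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square statistic (1 df) and its p-value."""
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / denom
    return chi2, float(stats.chi2.sf(chi2, df=1))


def multivariate_logistic(
    labels: SubgroupAssignment | Mapping[str, str],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Logistic regression of subgroup (up = 1) on clinical covariates.

    Complete-case analysis; the dropped-row count is attached as
    ``result.attrs['n_dropped']``.  Returns one row per covariate with
    the exponentiated coefficient (odds ratio), 95% Wald CI and p-value.
    Raises :class:`SeparationError` when the fit is degenerate.
    """
    import statsmodels.api as sm

    label_map = labels.label if isinstance(labels, SubgroupAssignment) else dict(labels)
    df = covariates.copy()
    df = df.loc[[s for s in df.index if s in label_map]]
    y = pd.Series({s: 1.0 if label_map[s] == "up" else 0.0 for s in df.index})
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    y = y.loc[complete.index]
    x = sm.add_constant(complete.astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, x).fit(disp=False, maxiter=100, tol=1e-8)
    except Exception as exc:  # PerfectSeparationError and numeric failures
        raise SeparationError(str(exc)) from exc
    probs = fit.predict(x)
    if ((probs < 1e-8) | (probs > 1 - 1e-8)).any() and np.abs(fit.params).max() > 15:
        raise SeparationError("fitted probabilities at 0/1 with diverging coefficient")
    out = pd.DataFrame(
        {
            "odds_ratio": np.exp(fit.params),
            "ci_low": np.exp(fit.params - Z_95 * fit.bse),
            "ci_high": np.exp(fit.params + Z_95 * fit.bse),
            "p_value": fit.pvalues,
        }
    ).drop(index="const")
    out.attrs["n_dropped"] = n_dropped
    out.attrs["converged"] = bool(fit.mle_retvals.get("converged", True))
    return out


# ---------------------------------------------------------------------------
# Survival


def _records_frame(records: pd.DataFrame) -> pd.DataFrame:
    req = {"time", "event"}
    if not req <= set(records.columns):
        raise ValueError(f"survival records need columns {sorted(req)}")
    if (records["time"] < 0).any():
        raise ValueError("negative survival time")
    return records


def kaplan_meier(
    records: pd.DataFrame, by: str = "group"
) -> SurvivalResult:
    """Product-limit survival curves, one per group.

    ``records`` needs ``time`` (days), ``event`` (1 = death, 0 =
    censored) and the grouping column.  Censoring tied with events is
    handled events-first (the standard product-limit convention).
    """
    records = _records_frame(records)
    result = SurvivalResult()
    for grp, sub in records.groupby(by, sort=True):
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        at_risk = [
            int((sub["time"] >= t).sum()) for t in curve["time"]
        ]
        curve["at_risk"] = at_risk
        result.curves[str(grp)] = curve
    if not result.curves:
        raise ValueError("no groups with records")
    return result


def logrank_test(records: pd.DataFrame, by: str = "group") -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    records = _records_frame(records)
    groups = sorted(records[by].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {groups}")
    if records["event"].sum() == 0:
        raise ValueError("no events observed")
    g0 = records[records[by] == groups[0]]
    g1 = records[records[by] == groups[1]]
    res = _ll_logrank(
        g0["time"], g1["time"], event_observed_A=g0["event"], event_observed_B=g1["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def cox_ph(
    records: pd.DataFrame,
    covariates: Sequence[str],
) -> SurvivalResult:
    """Cox proportional-hazards fit with Efron handling of tied times.

    Hazard ratios are exponentiated coefficients with 95% Wald CIs.  A
    stratum without events yields a monotone partial likelihood; the
    fitter's convergence failure is surfaced as ``ValueError``.
    """
    records = _records_frame(records)
    cols = ["time", "event", *covariates]
    df = records[cols].dropna().astype(float)
    if df["event"].sum() == 0:
        raise ValueError("no events observed")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    hr = pd.DataFrame(
        {
            "hazard_ratio": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef"] - Z_95 * summary["se(coef)"]),
            "ci_high": np.exp(summary["coef"] + Z_95 * summary["se(coef)"]),
            "p_value": summary["p"],
        }
    )
    return SurvivalResult(hazard_ratios=hr)


def per_gene_survival_screen(
    expr: FoldChangeMatrix,
    records: pd.DataFrame,
    module: GeneModule,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen each module gene for association with survival.

    For every module gene, cohort samples are dichotomised at that
    gene's median fold-change (above median = high expression) and a
    univariate Cox fit gives the hazard ratio of high vs low.  All
    genes are returned with raw p-values plus a Benjamini-Hochberg
    column; ``selected`` marks genes with raw p < ``alpha`` and HR > 1
    (up-regulation associated with poorer survival).
    """
    from statsmodels.stats.multitest import multipletests

    genes = sorted(g for g in module.members if g in set(expr.gene_ids))
    missing = sorted(module.members - set(genes))
    if missing:
        raise KeyError(f"module genes absent from cohort matrix: {missing[:10]}")
    rows = []
    records = _records_frame(records).set_index("sample_id") if "sample_id" in records.columns else _records_frame(records)
    shared = [s for s in expr.sample_ids if s in records.index]
    rec = records.loc[shared]
    for g in genes:
        vals = expr.values.loc[g, shared].astype(float)
        high = (vals > vals.median()).astype(float)
        df = pd.DataFrame(
            {"time": rec["time"].values, "event": rec["event"].values, "high": high.values}
        )
        try:
            res = cox_ph(df, ["high"])
            hr = float(res.hazard_ratios.loc["high", "hazard_ratio"])
            p = float(res.hazard_ratios.loc["high", "p_value"])
        except Exception:
            hr, p = float("nan"), float("nan")
        rows.append({"gene_id": g, "hazard_ratio": hr, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        pvals = out["p_value"].fillna(1.0).to_numpy()
        out["p_bh"] = multipletests(pvals, method="fdr_bh")[1]
        out["selected"] = (out["p_value"] < alpha) & (out["hazard_ratio"] > 1)
    else:
        out = pd.DataFrame(
            columns=["gene_id", "hazard_ratio", "p_value", "p_bh", "selected"]
        )
    return out
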
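import math

import numpy as np
import pandas as pd
import pytest

from scmodules.clinical_stats import (
    LADC_CLINICAL_TABLE,
    ContingencyTable2x2,
    SeparationError,
    cox_ph,
    kaplan_meier,
    logrank_test,
    multivariate_logistic,
    odds_ratio,
    per_gene_survival_screen,
    percent_breakdown,
    tabulate_2x2,
)
from scmodules.module_discovery import GeneModule
from scmodules.expression_io import FoldChangeMatrix


def survival_table() -> ContingencyTable2x2:
    a, b, c, d = LADC_CLINICAL_TABLE["survival"]["counts"]
    return ContingencyTable2x2(a, b, c, d, variable="survival")


class TestTabulate2x2:
    def test_counts_partition_and_missing_reported(self):
        labels = {f"s{i}": ("down" if i < 4 else "up") for i in range(8)}
        var = pd.Series(
            {"s0": "alive", "s1": "alive", "s2": "death", "s3": np.nan,
             "s4": "death", "s5": "alive", "s6": np.nan, "s7": "death"}
        )
        t = tabulate_2x2(labels, var, index_level="death", reference_level="alive")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
        assert t.n_missing == 2
        assert t.total == 6

    def test_all_missing_rejected(self):
        labels = {"s0": "up"}
        var = pd.Series({"s0": np.nan})
        with pytest.raises(ValueError):
            tabulate_2x2(labels, var, "x", "y")

    def test_non_dichotomous_rejected(self):
        labels = {"s0": "up"}
        var = pd.Series({"s0": "stage3"})
        with pytest.raises(ValueError, match="dichotomous"):
            tabulate_2x2(labels, var, "yes", "no")


class TestPercentBreakdown:
    def test_published_survival_row(self):
        pct = percent_breakdown(survival_table())
        assert pct == {
            "down_ref_pct": 82.5, "down_index_pct": 17.5,
            "up_ref_pct": 67.9, "up_index_pct": 32.1,
        }

    @pytest.mark.parametrize(
        "row,expected",
        [
            ("gender", (61.4, 38.6, 47.9, 52.1)),
            ("age", (63.3, 36.7, 50.0, 50.0)),
            ("stage", (83.7, 16.3, 71.8, 28.2)),
            ("tobacco_reformed", (55.2, 44.8, 28.3, 71.7)),
        ],
    )
    def test_remaining_published_rows(self, row, expected):
        a, b, c, d = LADC_CLINICAL_TABLE[row]["counts"]
        pct = percent_breakdown(ContingencyTable2x2(a, b, c, d))
        assert tuple(pct.values()) == expected

    def test_zero_cell_gives_zero_percent(self):
        pct = percent_breakdown(ContingencyTable2x2(5, 0, 3, 3))
        assert pct["down_index_pct"] == 0.0


class TestOddsRatio:
    def test_cross_product_on_survival_counts(self):
        res = odds_ratio(survival_table())
        assert res.odds_ratio == pytest.approx((75 * 188) / (40 * 159), rel=1e-12)
        assert round(res.odds_ratio, 3) == 2.217

    def test_chi_square_by_hand_formula(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 188, 40, 159, 75
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        res = odds_ratio(survival_table())
        assert res.chi_square == pytest.approx(expected, rel=1e-12)
        assert res.chi_square == pytest.approx(13.0, abs=0.01)
        assert res.p_value < 0.001

    def test_symmetric_table_is_null(self):
        res = odds_ratio(ContingencyTable2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.chi_square == 0.0

    def test_ci_matches_log_scale_closed_form(self):
        res = odds_ratio(survival_table())
        se = math.sqrt(1 / 188 + 1 / 40 + 1 / 159 + 1 / 75)
        assert res.ci_low == pytest.approx(math.exp(math.log(res.odds_ratio) - 1.959963984540054 * se))
        assert res.ci_high == pytest.approx(math.exp(math.log(res.odds_ratio) + 1.959963984540054 * se))
        # symmetric on the log scale
        assert math.log(res.ci_high) - math.log(res.odds_ratio) == pytest.approx(
            math.log(res.odds_ratio) - math.log(res.ci_low)
        )

    def test_zero_cell_triggers_continuity_correction(self):
        res = odds_ratio(ContingencyTable2x2(5, 0, 3, 3))
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)


class TestLogistic:
    def test_single_binary_covariate_reproduces_odds_ratio(self):
        # saturated 2x2 equivalence: logistic OR == cross-product OR
        t = survival_table()
        rows, ys = [], []
        for grp, count_ref, count_idx in (("down", t.a, t.b), ("up", t.c, t.d)):
            for _ in range(count_ref):
                rows.append(0.0); ys.append(grp)
            for _ in range(count_idx):
                rows.append(1.0); ys.append(grp)
        idx = [f"s{i}" for i in range(len(rows))]
        cov = pd.DataFrame({"death": rows}, index=idx)
        labels = dict(zip(idx, ys))
        fit = multivariate_logistic(labels, cov)
        assert fit.loc["death", "odds_ratio"] == pytest.approx(
            odds_ratio(t).odds_ratio, rel=1e-6
        )

    def test_separation_flagged(self):
        idx = [f"s{i}" for i in range(20)]
        labels = {s: ("up" if i < 10 else "down") for i, s in enumerate(idx)}
        cov = pd.DataFrame({"x": [1.0] * 10 + [0.0] * 10}, index=idx)
        with pytest.raises(SeparationError):
            multivariate_logistic(labels, cov)

    def test_true_or_recovered_in_simulation(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        logit = -0.5 + np.log(2.0) * x
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        idx = [f"s{i}" for i in range(n)]
        labels = {s: ("up" if yi else "down") for s, yi in zip(idx, y)}
        fit = multivariate_logistic(labels, pd.DataFrame({"x": x}, index=idx))
        assert fit.loc["x", "ci_low"] < 2.0 < fit.loc["x", "ci_high"]


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 0], "group": ["g"] * 3})
        curve = kaplan_meier(rec).curves["g"]
        s = dict(zip(curve["time"], curve["survival"]))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert s[3.0] == pytest.approx(1 / 3)

    def test_no_events_flat_curve(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0], "group": ["g"] * 3})
        curve = kaplan_meier(rec).curves["g"]
        assert (curve["survival"] == 1.0).all()

    def test_all_events_tied_single_drop(self):
        rec = pd.DataFrame({"time": [5, 5, 5], "event": [1, 1, 1], "group": ["g"] * 3})
        curve = kaplan_meier(rec).curves["g"]
        assert curve["survival"].iloc[-1] == pytest.approx(0.0)

    def test_curves_non_increasing_start_at_one(self):
        rng = np.random.default_rng(1)
        rec = pd.DataFrame({
            "time": rng.exponential(10, 50).round(2),
            "event": rng.integers(0, 2, 50),
            "group": ["a"] * 25 + ["b"] * 25,
        })
        for curve in kaplan_meier(rec).curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()

    def test_six_record_two_group_hand_check(self):
        rec = pd.DataFrame({
            "time": [2, 4, 4, 1, 3, 5],
            "event": [1, 0, 1, 1, 1, 0],
            "group": ["a", "a", "a", "b", "b", "b"],
        })
        curves = kaplan_meier(rec).curves
        sa = dict(zip(curves["a"]["time"], curves["a"]["survival"]))
        # group a: event at 2 (n=3), censor at 4, event at 4 (events-first: n=2)
        assert sa[2.0] == pytest.approx(2 / 3)
        assert sa[4.0] == pytest.approx(2 / 3 * 1 / 2)
        sb = dict(zip(curves["b"]["time"], curves["b"]["survival"]))
        assert sb[1.0] == pytest.approx(2 / 3)
        assert sb[3.0] == pytest.approx(1 / 3)
        assert sb[5.0] == pytest.approx(1 / 3)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        rec = pd.DataFrame({
            "time": [1, 2, 3, 1, 2, 3],
            "event": [1, 1, 0, 1, 1, 0],
            "group": ["a"] * 3 + ["b"] * 3,
        })
        stat, p = logrank_test(rec)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_toy(self):
        # events A@(1,2); B censored @(2,3): O-E tabulation gives 49/17
        rec = pd.DataFrame({
            "time": [1, 2, 2, 3],
            "event": [1, 1, 0, 0],
            "group": ["A", "A", "B", "B"],
        })
        stat, _ = logrank_test(rec)
        assert stat == pytest.approx(49 / 17, rel=1e-9)

    def test_invariant_under_time_rescaling(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame({
            "time": rng.exponential(5, 40),
            "event": rng.integers(0, 2, 40),
            "group": ["a"] * 20 + ["b"] * 20,
        })
        stat1, _ = logrank_test(rec)
        rec2 = rec.assign(time=rec["time"] * 2)
        stat2, _ = logrank_test(rec2)
        assert stat1 == pytest.approx(stat2, rel=1e-12)


class TestCox:
    def test_two_group_exponential_recovery(self):
        rng = np.random.default_rng(5)
        n = 400
        up = rng.random(n) < 0.4
        lam = 0.01 * np.where(up, 2.0, 1.0)
        t = rng.exponential(1 / lam)
        c = rng.exponential(1 / 0.004, n)
        rec = pd.DataFrame({
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "up": up.astype(float),
        })
        res = cox_ph(rec, ["up"])
        row = res.hazard_ratios.loc["up"]
        assert row["ci_low"] < 2.0 < row["ci_high"]

    def test_independent_covariate_hr_near_one(self):
        rng = np.random.default_rng(6)
        n = 500
        rec = pd.DataFrame({
            "time": rng.exponential(100, n),
            "event": np.ones(n, dtype=int),
            "x": rng.normal(size=n),
        })
        row = cox_ph(rec, ["x"]).hazard_ratios.loc["x"]
        assert 0.8 < row["hazard_ratio"] < 1.25

    def test_no_events_rejected(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError):
            cox_ph(rec, ["x"])


class TestPerGeneScreen:
    @staticmethod
    def _cohort(seed, n=200, n_genes=10, prognostic=5, hr=2.5):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        state = rng.random(n) < 0.5
        vals = rng.normal(0, 1, (n_genes, n))
        vals[:prognostic] += np.where(state, 1.5, -1.5)
        genes = [f"g{i}" for i in range(n_genes)]
        fc = FoldChangeMatrix(
            values=pd.DataFrame(vals, index=genes, columns=samples),
            over=samples, floor=0.1,
            floored_mean=pd.Series(1.0, index=genes),
            expressed=pd.DataFrame(True, index=genes, columns=samples),
        )
        lam = 0.01 * np.where(state, hr, 1.0)
        t = rng.exponential(1 / lam)
        c = rng.exponential(250, n)
        rec = pd.DataFrame({
            "sample_id": samples,
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        })
        module = GeneModule(seed_genes=set(), members=set(genes))
        return fc, rec, module, genes[:prognostic]

    def test_planted_prognostic_genes_recovered(self):
        hits = 0
        for seed in range(10):
            fc, rec, module, planted = self._cohort(seed)
            out = per_gene_survival_screen(fc, rec, module)
            found = set(out[out["selected"]]["gene_id"])
            hits += set(planted) <= found
        assert hits >= 9

    def test_permuted_times_false_positive_rate(self):
        rng = np.random.default_rng(42)
        fp = []
        for seed in range(10):
            fc, rec, module, _ = self._cohort(seed, prognostic=0)
            rec = rec.assign(time=rng.permutation(rec["time"].to_numpy()))
            out = per_gene_survival_screen(fc, rec, module)
            # two-sided p < alpha occurs at ~alpha; HR>1 halves that
            fp.append((out["p_value"] < 0.05).mean())
        assert np.mean(fp) < 0.15

    def test_empty_module_gives_empty_frame(self):
        fc, rec, _, _ = self._cohort(0)
        module = GeneModule(seed_genes=set(), members=set())
        out = per_gene_survival_screen(fc, rec, module)
        assert len(out) == 0
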
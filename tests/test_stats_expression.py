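"""Welch screening, region ANOVA, ddCt expression and correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from methylotrace import synthetic_data as sd
from methylotrace.stats_expression import (RegionTable, bonferroni,
                                           ddct_expression, region_anova,
                                           region_expression_correlation,
                                           sitewise_tests)
from helpers import make_profile_frame


def welch_oracle(x, y):
    """Textbook Welch t and Satterthwaite-df p (independent formula)."""
    from scipy.stats import t as tdist
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx ** 2 / (len(x) - 1) + vy ** 2 / (len(y) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


class TestSitewiseTests:
    def test_identical_groups_give_p_one(self):
        frame = make_profile_frame({("PND14", 1): 50.0, ("PND35", 1): 50.0})
        res = sitewise_tests(frame)
        assert (res["p"] == 1.0).all()
        assert not res["significant"].any()

    def test_matches_textbook_welch_computation(self):
        x, y = [42.1, 44.9, 43.5], [47.2, 48.8, 46.1]
        rows = []
        for stage, vals in (("PND14", x), ("PND35", y)):
            for i, v in enumerate(vals):
                rows.append((f"{stage}_a{i}", stage, "CpG1", 1, v, "ok", 1, 1))
        frame = pd.DataFrame(rows, columns=["sample", "stage", "cpg_id",
                                            "region_id", "percent", "flag",
                                            "i_c", "i_t"])
        res = sitewise_tests(frame).iloc[0]
        t, p = welch_oracle(x, y)
        assert res["t"] == pytest.approx(t, abs=1e-10)
        assert res["p"] == pytest.approx(p, abs=1e-10)

    def test_degenerate_zero_variance_unequal_means(self):
        frame = make_profile_frame({("PND14", 1): 40.0, ("PND35", 1): 50.0})
        res = sitewise_tests(frame)
        assert (res["note"] == "degenerate").all()
        assert (res["p"] == 0.0).all()

    def test_uncovered_site_skipped_and_reported(self):
        frame = make_profile_frame({("PND14", 1): 50.0, ("PND35", 1): 55.0},
                                   sd=1.0)
        frame.loc[frame["cpg_id"] == "CpG_r1_0", "flag"] = "insufficient"
        res = sitewise_tests(frame)
        assert "CpG_r1_0" in res.attrs["skipped_sites"]
        assert "CpG_r1_0" not in set(res["cpg_id"])


class TestRegionAnova:
    def test_planted_effect_detected_with_bonferroni_posthoc(self):
        means = {("PND14", 2): 42.0, ("PND35", 2): 47.0, ("PND56", 2): 48.0}
        frame = make_profile_frame(means, sd=1.5, seed=3, sites_per_region=9)
        (res,) = region_anova(frame)
        assert res.omnibus_p < 0.05
        p14_35 = res.pairwise.set_index(["stage_a", "stage_b"])
        assert p14_35.loc[("PND14", "PND35"), "p_adj"] < 0.05
        assert p14_35.loc[("PND14", "PND35"), "diff"] == pytest.approx(5.0, abs=3.0)

    def test_mixed_and_oneway_modes_agree_on_balanced_data(self):
        means = {("PND14", 1): 60.0, ("PND35", 1): 66.0, ("PND56", 1): 67.0}
        frame = make_profile_frame(means, sd=2.0, seed=4, sites_per_region=5)
        (mixed,) = region_anova(frame, mode="mixed")
        (oneway,) = region_anova(frame, mode="oneway")
        # between-animal F of the mixed design equals the one-way ANOVA
        # on animal-level means when the design is balanced
        assert mixed.omnibus_p == pytest.approx(oneway.omnibus_p, rel=1e-6)

    def test_incomplete_site_dropped_from_omnibus(self):
        means = {("PND14", 1): 50.0, ("PND35", 1): 55.0, ("PND56", 1): 56.0}
        frame = make_profile_frame(means, sd=1.0, seed=5, sites_per_region=4)
        mask = (frame["cpg_id"] == "CpG_r1_0") & (frame["sample"] == "PND14_a1")
        frame.loc[mask, "flag"] = "insufficient"
        (res,) = region_anova(frame)
        assert res.n_sites == 3  # the incompletely covered site is excluded

    def test_type_i_error_near_nominal_under_null(self):
        rejections = 0
        n_cohorts = 120
        for seed in range(n_cohorts):
            frame = make_profile_frame({(s, 2): 50.0 for s in sd.STAGES},
                                       sd=3.0, seed=seed, sites_per_region=5)
            (res,) = region_anova(frame)
            rejections += res.omnibus_p < 0.05
        assert rejections / n_cohorts == pytest.approx(0.05, abs=0.06)


class TestBonferroni:
    def test_multiplies_and_caps(self):
        assert bonferroni(0.02, 3) == pytest.approx(0.06)
        assert bonferroni(0.5, 3) == 1.0

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)


class TestDdctExpression:
    def _ct_table(self, folds, noise=0.0, seed=0):
        design = sd.CohortDesign(expression_fold=folds)
        return sd.simulate_qpcr(design, ct_noise_sd=noise, seed=seed)

    def test_zero_ddct_gives_rq_one(self):
        ct = self._ct_table({s: 1.0 for s in sd.STAGES})
        res = ddct_expression(ct)
        np.testing.assert_allclose(res.per_sample["rq"], 1.0)

    def test_known_fold_recovered_exactly_without_noise(self):
        ct = self._ct_table({"PND14": 1.0, "PND35": 0.3, "PND56": 0.3})
        res = ddct_expression(ct)
        by_stage = res.per_stage.set_index("stage")["mean_rq"]
        assert by_stage["PND14"] == pytest.approx(1.0)
        assert by_stage["PND35"] == pytest.approx(0.3)
        # ddCt of the pubertal drop: log2(1/0.3)
        pnd35 = res.per_sample[res.per_sample["stage"] == "PND35"]
        assert pnd35["ddct"].mean() == pytest.approx(math.log2(1 / 0.3), abs=1e-9)

    def test_calibrator_stage_mean_is_one_by_construction(self):
        ct = self._ct_table({"PND14": 1.0, "PND35": 0.4, "PND56": 0.5},
                            noise=0.3, seed=5)
        res = ddct_expression(ct)
        cal = res.per_sample[res.per_sample["stage"] == "PND14"]
        # mean ddCt of calibrator is 0, so geometric-mean RQ is 1
        assert cal["ddct"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_shift_invariance_of_relative_quantities(self):
        ct = self._ct_table({"PND14": 1.0, "PND35": 0.3, "PND56": 0.3},
                            noise=0.2, seed=6)
        shifted = ct.copy()
        shifted["ct"] += 3.7  # plate-wide shift hits both genes equally
        r1, r2 = ddct_expression(ct), ddct_expression(shifted)
        np.testing.assert_allclose(r1.per_sample["rq"], r2.per_sample["rq"])

    def test_anova_and_tukey_flag_the_drop(self):
        ct = self._ct_table({"PND14": 1.0, "PND35": 0.3, "PND56": 0.3},
                            noise=0.1, seed=7)
        res = ddct_expression(ct)
        assert res.anova_p < 0.01
        tuk = res.tukey.set_index(["stage_a", "stage_b"])["p_adj"]
        assert tuk[("PND14", "PND35")] < 0.05
        assert tuk[("PND35", "PND56")] > 0.05

    def test_missing_reference_gene_drops_sample(self):
        ct = self._ct_table({s: 1.0 for s in sd.STAGES})
        ct = ct[~((ct["sample"] == "PND14_a1") & (ct["gene"] == "Actb"))]
        with pytest.warns(UserWarning, match="PND14_a1"):
            res = ddct_expression(ct)
        assert "PND14_a1" not in set(res.per_sample["sample"])
        assert res.dropped_samples == ["PND14_a1"]


class TestRegionExpressionCorrelation:
    def _expression(self, rq_by_sample):
        per_sample = pd.DataFrame({
            "sample": list(rq_by_sample), "stage": "x",
            "dct": 0.0, "ddct": 0.0, "rq": list(rq_by_sample.values())})
        from methylotrace.stats_expression import ExpressionResult
        return ExpressionResult(per_sample=per_sample, per_stage=pd.DataFrame(),
                                anova_p=None, tukey=pd.DataFrame(),
                                calibrator_stage="x")

    def test_perfect_anticorrelation(self):
        rows = []
        for i, (meth, rq) in enumerate(zip([40, 45, 50, 55], [1.0, 0.8, 0.6, 0.4])):
            rows.append((f"s{i}", "x", "CpG1", 2, float(meth), "ok", 1, 1))
        frame = pd.DataFrame(rows, columns=["sample", "stage", "cpg_id",
                                            "region_id", "percent", "flag",
                                            "i_c", "i_t"])
        expr = self._expression({f"s{i}": rq
                                 for i, rq in enumerate([1.0, 0.8, 0.6, 0.4])})
        res = region_expression_correlation(frame, expr)
        assert res["pearson_r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        meth = [40.0, 47.0, 44.0, 52.0]
        rq = [1.0, 0.5, 0.8, 0.35]
        rows = [(f"s{i}", "x", "CpG1", 1, m, "ok", 1, 1)
                for i, m in enumerate(meth)]
        frame = pd.DataFrame(rows, columns=["sample", "stage", "cpg_id",
                                            "region_id", "percent", "flag",
                                            "i_c", "i_t"])
        expr = self._expression({f"s{i}": r for i, r in enumerate(rq)})
        res = region_expression_correlation(frame, expr)
        x, y = np.array(meth), np.array(rq)
        r_oracle = (((x - x.mean()) * (y - y.mean())).sum()
                    / math.sqrt(((x - x.mean()) ** 2).sum()
                                * ((y - y.mean()) ** 2).sum()))
        assert res["pearson_r"].iloc[0] == pytest.approx(r_oracle, abs=1e-12)

    def test_affine_rescale_flips_sign_with_negative_scale(self):
        meth = [40.0, 47.0, 44.0, 52.0]
        rq = {f"s{i}": r for i, r in enumerate([1.0, 0.5, 0.8, 0.35])}
        rows = [(f"s{i}", "x", "CpG1", 1, m, "ok", 1, 1)
                for i, m in enumerate(meth)]
        frame = pd.DataFrame(rows, columns=["sample", "stage", "cpg_id",
                                            "region_id", "percent", "flag",
                                            "i_c", "i_t"])
        r1 = region_expression_correlation(frame, self._expression(rq))
        flipped = {k: -2.0 * v + 7.0 for k, v in rq.items()}
        r2 = region_expression_correlation(frame, self._expression(flipped))
        assert r2["pearson_r"].iloc[0] == pytest.approx(
            -r1["pearson_r"].iloc[0], abs=1e-12)

    def test_fewer_than_three_pairs_not_evaluable(self):
        rows = [("s0", "x", "CpG1", 1, 40.0, "ok", 1, 1),
                ("s1", "x", "CpG1", 1, 50.0, "ok", 1, 1)]
        frame = pd.DataFrame(rows, columns=["sample", "stage", "cpg_id",
                                            "region_id", "percent", "flag",
                                            "i_c", "i_t"])
        expr = self._expression({"s0": 1.0, "s1": 0.5})
        res = region_expression_correlation(frame, expr)
        assert np.isnan(res["pearson_r"].iloc[0])


class TestRegionTable:
    def test_default_mkrn3_regions_ordered_disjoint(self):
        table = RegionTable.mkrn3()
        assert table.assign(-500) == 1
        assert table.assign(-100) == 2
        assert table.assign(-10) == 3
        assert table.assign(50) == 4
        assert table.assign(120) == 5
        assert table.assign(-250) is None  # gap between regions 1 and 2

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            RegionTable(spans={1: (-100, -50), 2: (-60, -10)})
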
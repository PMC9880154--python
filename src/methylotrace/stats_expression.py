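"""Stage statistics for region-grouped methylation and qPCR expression.

Three layers of inference mirror a typical promoter-methylation study
across developmental stages:

* **site-wise screening** — two-sided Welch t-tests per CpG for each
  stage pair, reported unadjusted (a screen, not a confirmatory test);
* **region-level ANOVA** — CpG sites grouped into promoter regions; the
  default model treats stage as a between-animal factor and site as the
  repeated measure within each animal (mixed-design ANOVA), with an
  animal-level-means one-way ANOVA available as an alternative mode.
  Pairwise stage comparisons use animal-level region means with
  Bonferroni adjustment;
* **expression** — ΔΔCt relative quantification (replicates averaged,
  ΔCt = Ct_target − Ct_reference, calibrated to the first stage,
  RQ = 2^−ΔΔCt) with one-way ANOVA and Tukey HSD across stages, and a
  per-animal Pearson correlation between region methylation and RQ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .methylation import FLAG_OK

#: the five-region grouping of the studied mouse Mkrn3 locus, as
#: TSS-relative spans of the member CpG positions (regions 1-3 promoter,
#: 4 the 5'UTR, 5 the first 50 nt of CDS; region 2 contains the islet)
MKRN3_REGION_SPANS = {
    1: (-716, -321),
    2: (-225, -83),
    3: (-42, -5),
    4: (1, 100),
    5: (101, 150),
}


@dataclass
class RegionTable:
    """Non-overlapping, 5'->3' ordered grouping of CpGs into regions."""

    spans: dict[int, tuple[int, int]]

    def __post_init__(self) -> None:
        items = sorted(self.spans.items())
        for (_, (lo1, hi1)), (_, (lo2, _)) in zip(items, items[1:]):
            if hi1 >= lo2:
                raise ValueError("region spans overlap or are unordered")
        for rid, (lo, hi) in items:
            if lo > hi:
                raise ValueError(f"region {rid} span reversed")

    @classmethod
    def mkrn3(cls) -> "RegionTable":
        return cls(spans=dict(MKRN3_REGION_SPANS))

    def assign(self, tss_rel: int) -> int | None:
        for rid, (lo, hi) in self.spans.items():
            if lo <= tss_rel <= hi:
                return rid
        return None


# ---------------------------------------------------------------------------
# site-wise Welch screening

def _stage_pairs(stages: list[str]) -> list[tuple[str, str]]:
    return list(combinations(stages, 2))


def sitewise_tests(profiles: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Welch t per CpG and stage pair on per-animal percentages.

    ``profiles`` is the tidy frame (sample, stage, cpg_id, percent,
    flag, ...). Sites with fewer than 2 covered animals in either group
    are skipped with note ``insufficient``; zero-variance degeneracies
    follow the conventions p=1 (equal means) / p=0 flagged ``degenerate``
    (unequal means).
    """
    usable = profiles[profiles["flag"] == FLAG_OK]
    stages = list(dict.fromkeys(profiles["stage"]))
    rows = []
    for cpg_id, grp in usable.groupby("cpg_id", sort=False):
        for s1, s2 in _stage_pairs(stages):
            x = grp.loc[grp["stage"] == s1, "percent"].to_numpy(dtype=float)
            y = grp.loc[grp["stage"] == s2, "percent"].to_numpy(dtype=float)
            if len(x) < 2 or len(y) < 2:
                rows.append((cpg_id, s1, s2, np.nan, np.nan, False, "insufficient"))
                continue
            if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
                if np.isclose(x.mean(), y.mean()):
                    rows.append((cpg_id, s1, s2, 0.0, 1.0, False, "zero-variance"))
                else:
                    rows.append((cpg_id, s1, s2, np.inf, 0.0, True, "degenerate"))
                continue
            t, p = stats.ttest_ind(x, y, equal_var=False)
            rows.append((cpg_id, s1, s2, float(t), float(p), bool(p < alpha), ""))
    out = pd.DataFrame(rows, columns=["cpg_id", "stage_a", "stage_b",
                                      "t", "p", "significant", "note"])
    skipped = sorted(set(profiles["cpg_id"]) - set(usable["cpg_id"]))
    out.attrs["skipped_sites"] = skipped
    return out


# ---------------------------------------------------------------------------
# region-grouped ANOVA

@dataclass
class RegionAnovaResult:
    region_id: int
    omnibus_p: float | None
    omnibus_f: float | None
    n_sites: int
    pairwise: pd.DataFrame  # stage_a, stage_b, diff, p_raw, p_adj
    note: str = ""


def _animal_region_means(region_df: pd.DataFrame) -> pd.DataFrame:
    return (region_df.groupby(["stage", "sample"], sort=False)["percent"]
            .mean().reset_index())


def region_anova(profiles: pd.DataFrame,
                 region_table: RegionTable | None = None,
                 mode: str = "mixed", alpha: float = 0.05) -> list[RegionAnovaResult]:
    """Per-region stage comparison with Bonferroni-adjusted post hoc.

    mode="mixed": stage is between-animal, CpG site the repeated
    measure within each animal (sites with incomplete coverage across
    animals are dropped from the omnibus). mode="oneway": one-way ANOVA
    on animal-level region means. Pairwise post-hoc tests always run on
    animal-level region means; raw p-values are multiplied by the
    number of comparisons (capped at 1).
    """
    if mode not in ("mixed", "oneway"):
        raise ValueError("mode must be 'mixed' or 'oneway'")
    usable = profiles[profiles["flag"] == FLAG_OK].copy()
    stages = list(dict.fromkeys(profiles["stage"]))
    results = []
    for region_id, region_df in usable.groupby("region_id", sort=True):
        n_animals = region_df["sample"].nunique()
        # sites covered in every animal (balanced within-factor)
        counts = region_df.groupby("cpg_id")["sample"].nunique()
        complete_sites = counts[counts == n_animals].index
        complete = region_df[region_df["cpg_id"].isin(complete_sites)]
        note = ""
        omnibus_p = omnibus_f = None
        per_stage_n = complete.groupby("stage")["sample"].nunique()
        evaluable = (len(complete_sites) >= 1
                     and all(per_stage_n.get(s, 0) >= 2 for s in stages))
        if mode == "mixed" and len(complete_sites) < 2:
            note = "fewer than 2 complete sites; omnibus not evaluable"
            evaluable = False
        if evaluable:
            if mode == "mixed":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    table = pg.mixed_anova(data=complete, dv="percent",
                                           within="cpg_id", subject="sample",
                                           between="stage")
                row = table[table["Source"] == "stage"].iloc[0]
                omnibus_p, omnibus_f = float(row["p_unc"]), float(row["F"])
            else:
                means = _animal_region_means(complete)
                groups = [g["percent"].to_numpy() for _, g in means.groupby("stage")]
                f, p = stats.f_oneway(*groups)
                omnibus_p, omnibus_f = float(p), float(f)
        elif not note:
            note = "insufficient animals per stage; omnibus not evaluable"

        means = _animal_region_means(region_df)
        pairs = _stage_pairs(stages)
        prows = []
        for s1, s2 in pairs:
            x = means.loc[means["stage"] == s1, "percent"].to_numpy()
            y = means.loc[means["stage"] == s2, "percent"].to_numpy()
            if len(x) < 2 or len(y) < 2:
                prows.append((s1, s2, np.nan, np.nan, np.nan, False))
                continue
            t, p = stats.ttest_ind(x, y, equal_var=False)
            p_adj = min(1.0, float(p) * len(pairs))
            prows.append((s1, s2, float(y.mean() - x.mean()), float(p), p_adj,
                          bool(p_adj < alpha)))
        pairwise = pd.DataFrame(prows, columns=["stage_a", "stage_b", "diff",
                                                "p_raw", "p_adj", "significant"])
        results.append(RegionAnovaResult(region_id=int(region_id),
                                         omnibus_p=omnibus_p, omnibus_f=omnibus_f,
                                         n_sites=len(complete_sites),
                                         pairwise=pairwise, note=note))
    return results


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni adjustment: p * n, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return min(1.0, p * n_comparisons)


# ---------------------------------------------------------------------------
# ddCt expression

@dataclass
class ExpressionResult:
    per_sample: pd.DataFrame   # sample, stage, dct, ddct, rq
    per_stage: pd.DataFrame    # stage, mean_rq, sd_rq, n
    anova_p: float | None
    tukey: pd.DataFrame        # stage_a, stage_b, p_adj
    calibrator_stage: str
    dropped_samples: list[str] = field(default_factory=list)


def ddct_expression(ct_table: pd.DataFrame, target_gene: str = "Mkrn3",
                    reference_gene: str = "Actb",
                    calibrator_stage: str | None = None) -> ExpressionResult:
    """ΔΔCt relative quantification with one-way ANOVA + Tukey HSD.

    Replicate wells are averaged per sample and gene; ΔCt = Ct_target −
    Ct_reference; ΔΔCt subtracts the calibrator stage's mean ΔCt; the
    relative quantity is 2^−ΔΔCt (calibrator stage mean = 1 by
    construction). Samples missing either gene are dropped with a
    warning.
    """
    stages = list(dict.fromkeys(ct_table["stage"]))
    calibrator = calibrator_stage or stages[0]
    mean_ct = (ct_table.groupby(["sample", "stage", "gene"], sort=False)["ct"]
               .mean().reset_index())
    wide = mean_ct.pivot_table(index=["sample", "stage"], columns="gene",
                               values="ct").reset_index()
    dropped = []
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    bad = wide[target_gene].isna() | wide[reference_gene].isna()
    if bad.any():
        dropped = sorted(wide.loc[bad, "sample"])
        warnings.warn(f"dropping samples with missing wells: {dropped}")
        wide = wide[~bad]
    wide = wide.copy()
    wide["dct"] = wide[target_gene] - wide[reference_gene]
    cal_mean = wide.loc[wide["stage"] == calibrator, "dct"].mean()
    if np.isnan(cal_mean):
        raise ValueError(f"no usable samples in calibrator stage {calibrator!r}")
    wide["ddct"] = wide["dct"] - cal_mean
    wide["rq"] = 2.0 ** (-wide["ddct"])
    per_sample = wide[["sample", "stage", "dct", "ddct", "rq"]]
    per_stage = (per_sample.groupby("stage", sort=False)["rq"]
                 .agg(mean_rq="mean", sd_rq="std", n="count").reset_index())
    groups = [g["rq"].to_numpy() for _, g in per_sample.groupby("stage", sort=False)]
    anova_p = None
    tukey_rows = []
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        _, anova_p = stats.f_oneway(*groups)
        anova_p = float(anova_p)
        res = stats.tukey_hsd(*groups)
        for i, j in combinations(range(len(stages)), 2):
            tukey_rows.append((stages[i], stages[j], float(res.pvalue[i, j])))
    tukey = pd.DataFrame(tukey_rows, columns=["stage_a", "stage_b", "p_adj"])
    return ExpressionResult(per_sample=per_sample, per_stage=per_stage,
                            anova_p=anova_p, tukey=tukey,
                            calibrator_stage=calibrator, dropped_samples=dropped)


# ---------------------------------------------------------------------------
# methylation x expression correlation

def region_expression_correlation(profiles: pd.DataFrame,
                                  expression: ExpressionResult) -> pd.DataFrame:
    """Per-region Pearson r between animal methylation and expression.

    Pairs animal-level region mean methylation with the same animal's
    relative quantity (per-animal pairing, n = animals across all
    stages). Regions with fewer than 3 paired animals are reported as
    not evaluable (r = NaN).
    """
    usable = profiles[profiles["flag"] == FLAG_OK]
    rq = expression.per_sample.set_index("sample")["rq"]
    rows = []
    for region_id, region_df in usable.groupby("region_id", sort=True):
        means = _animal_region_means(region_df).set_index("sample")["percent"]
        common = means.index.intersection(rq.index)
        if len(common) < 3:
            rows.append((int(region_id), np.nan, np.nan, len(common)))
            continue
        r, p = stats.pearsonr(means.loc[common], rq.loc[common])
        rows.append((int(region_id), float(r), float(p), len(common)))
    return pd.DataFrame(rows, columns=["region_id", "pearson_r", "p", "n_pairs"])
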
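"""Comparative-CT relative quantification and group-comparison statistics.

Relative expression follows the 2^-ddCt rule: dCt = Ct_target - Ct_reference
per sample, ddCt subtracts the reference group's mean dCt (per assay and
context), and rq = 2^-ddCt.  Group comparisons mirror a standard validation
workflow: for two groups, Shapiro-Wilk normality per group decides between a
rank-sum test and a t test whose equal-variance flavour is picked by
median-centered Levene; for more than two groups, Levene decides between
one-way ANOVA with Tukey HSD and Welch's ANOVA with Games-Howell pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats


@dataclass
class GroupComparison:
    groups: list[str]
    test_used: str  # t_equal | t_welch | wilcoxon | anova | welch_anova
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None  # pairwise adjusted p (when >2 groups)
    diagnostics: dict = field(default_factory=dict)


def comparative_ct(records: pd.DataFrame, reference_group: str = "young") -> pd.DataFrame:
    """Per-sample 2^-ddCt relative expression against a reference group.

    ddCt is computed within each (target assay, organ/cell context); the
    reference group's mean ddCt is 0 by construction, so its mean relative
    expression centers on 1.  ``rq_ref_only`` = 2^-dCt is also emitted for
    heat-map style reporting normalized to the reference assay alone.
    """
    req = {"sample_id", "group", "organ_or_celltype", "target_assay",
           "ct_target", "ct_reference"}
    if not req <= set(records.columns):
        raise ValueError(f"Ct table needs columns {sorted(req)}")
    out = []
    for (assay, ctx), grp in records.groupby(
        ["target_assay", "organ_or_celltype"], sort=True
    ):
        if grp["ct_target"].isna().any() or grp["ct_reference"].isna().any():
            raise ValueError(f"missing Ct for assay {assay} in {ctx}")
        ref = grp[grp["group"] == reference_group]
        if ref.empty:
            raise ValueError(
                f"reference group {reference_group!r} empty for {assay}/{ctx}"
            )
        dct = grp["ct_target"] - grp["ct_reference"]
        ref_mean = float((ref["ct_target"] - ref["ct_reference"]).mean())
        ddct = dct - ref_mean
        res = grp[["sample_id", "group", "organ_or_celltype", "target_assay"]].copy()
        res["delta_ct"] = dct
        res["delta_delta_ct"] = ddct
        res["rq"] = 2.0 ** (-ddct)
        res["rq_ref_only"] = 2.0 ** (-dct)
        out.append(res)
    return pd.concat(out, ignore_index=True)


def group_summary(rq: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and SEM of relative expression per assay/context/group."""
    g = rq.groupby(["target_assay", "organ_or_celltype", "group"])["rq"]
    return g.agg(
        mean_rq="mean",
        sd_rq="std",
        sem_rq=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
        n="size",
    ).reset_index()


def _games_howell(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    res = pg.pairwise_gameshowell(
        data=pd.DataFrame({"y": values, "g": labels}), dv="y", between="g"
    )
    return pd.DataFrame(
        {
            "group_a": res["A"],
            "group_b": res["B"],
            "statistic": res["T"],
            "p_adj": res["pval"],
        }
    )


def select_and_test(
    values: np.ndarray,
    groups: np.ndarray,
    alpha_normality: float = 0.05,
    alpha_variance: float = 0.05,
) -> GroupComparison:
    """Pick and run the appropriate group-comparison test.

    Two groups: any Shapiro-Wilk p below ``alpha_normality`` routes to the
    two-sample rank-sum (Wilcoxon/Mann-Whitney) test; otherwise
    median-centered Levene picks pooled vs Welch t.  More than two groups:
    Levene picks one-way ANOVA (with Tukey HSD pairs) vs Welch's ANOVA (with
    Games-Howell pairs).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = list(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) < 3 for s in samples):
        raise ValueError("need >= 3 values per group")
    diagnostics: dict = {}

    if len(uniq) == 2:
        a, b = samples
        normal_p = [float(stats.shapiro(s).pvalue) for s in samples]
        diagnostics["shapiro_p"] = normal_p
        if min(normal_p) < alpha_normality:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            return GroupComparison(
                uniq, "wilcoxon", float(res.statistic), float(res.pvalue),
                diagnostics=diagnostics,
            )
        lev_p = float(stats.levene(a, b, center="median").pvalue)
        diagnostics["levene_p"] = lev_p
        equal_var = lev_p >= alpha_variance
        if np.array_equal(a, b):
            return GroupComparison(uniq, "t_equal" if equal_var else "t_welch",
                                   0.0, 1.0, diagnostics=diagnostics)
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        return GroupComparison(
            uniq,
            "t_equal" if equal_var else "t_welch",
            float(res.statistic),
            float(res.pvalue),
            diagnostics=diagnostics,
        )

    lev_p = float(stats.levene(*samples, center="median").pvalue)
    diagnostics["levene_p"] = lev_p
    if lev_p >= alpha_variance:
        res = stats.f_oneway(*samples)
        tuk = stats.tukey_hsd(*samples)
        pairs = []
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                pairs.append(
                    {
                        "group_a": uniq[i],
                        "group_b": uniq[j],
                        "statistic": float(tuk.statistic[i, j]),
                        "p_adj": float(tuk.pvalue[i, j]),
                    }
                )
        return GroupComparison(
            uniq, "anova", float(res.statistic), float(res.pvalue),
            posthoc=pd.DataFrame(pairs), diagnostics=diagnostics,
        )
    wa = pg.welch_anova(
        data=pd.DataFrame({"y": values, "g": labels}), dv="y", between="g"
    )
    return GroupComparison(
        uniq,
        "welch_anova",
        float(wa["F"].iloc[0]),
        float(wa["p_unc"].iloc[0]),
        posthoc=_games_howell(values, labels),
        diagnostics=diagnostics,
    )


def compare_groups_per_assay(
    rq: pd.DataFrame, value_col: str = "rq"
) -> pd.DataFrame:
    """Run select_and_test for every assay x context; tidy result table."""
    rows = []
    for (assay, ctx), grp in rq.groupby(["target_assay", "organ_or_celltype"]):
        comp = select_and_test(grp[value_col].to_numpy(), grp["group"].to_numpy())
        rows.append(
            {
                "target_assay": assay,
                "organ_or_celltype": ctx,
                "test_used": comp.test_used,
                "statistic": comp.statistic,
                "pvalue": comp.pvalue,
            }
        )
    return pd.DataFrame(rows)
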
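"""Per-organ young-vs-old differential expression on bulk counts and the
cross-organ intersection that ranks consensus-target genes.

Expression is log2 counts-per-million with a pseudo-count; testing uses an
empirical-Bayes moderated t statistic: per-gene residual variances are
shrunk toward a common prior whose degrees of freedom and scale are
estimated by moment matching on log variances (an F-distribution fit via
digamma/trigamma equations).  Organ-level calls use raw p-values with a
linear fold-change floor, and candidate genes are ranked by the number of
organs in which they are called up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CountMatrix


@dataclass
class OrganDEParams:
    p_threshold: float = 0.05
    fold_threshold: float = 1.1  # linear scale
    prior_count: float = 0.5
    cpm_floor: float = 1.0  # genes with mean CPM below this are dropped

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")


@dataclass
class CrossOrganHit:
    gene: str
    organs_up: list[str]
    in_consensus_pathway_targets: bool = True

    @property
    def n_organs_up(self) -> int:
        return len(self.organs_up)


# ---------------------------------------------------------------------------
# log-CPM
# ---------------------------------------------------------------------------


def logcpm(
    counts: pd.DataFrame, prior_count: float = 0.5, cpm_floor: float | None = 1.0
) -> pd.DataFrame:
    """log2((count + prior) / (libsize + 2 prior) * 1e6), low-CPM genes dropped.

    The floor applies to the plain (un-priored) mean CPM across samples;
    pass ``cpm_floor=None`` to keep everything.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if cpm_floor is not None:
        mean_cpm = (counts / lib * 1e6).mean(axis=1)
        counts = counts.loc[mean_cpm >= cpm_floor]
    return np.log2((counts + prior_count) / (lib + 2 * prior_count) * 1e6)


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for x with trigamma(x) = y
    if y <= 0:
        return math.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = max(x + dif, 1e-8)
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match prior df d0 and scale s0^2 of the variance distribution.

    Models s^2 ~ s0^2 F(df, d0) and solves the mean/variance equations of
    log s^2 with digamma/trigamma.  Returns (d0, s0_sq); d0 = inf when the
    observed spread of log variances is no wider than chi-square sampling
    noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return math.inf, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2)
    e_mean = z.mean() - special.digamma(df / 2) + math.log(df / 2)
    e_var = z.var(ddof=1) - special.polygamma(1, df / 2)
    if e_var <= 0:
        return math.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2) - math.log(d0 / 2))
    )
    return float(d0), s0_sq


def moderated_ttest(
    log_expr: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    ref_group: str = "young",
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Two-group empirical-Bayes moderated t per gene.

    ``d0_override`` forces the prior degrees of freedom: 0 recovers the
    ordinary two-sample t, inf gives full shrinkage to the common variance.
    """
    labels = np.asarray(groups)
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    g0 = ref_group if ref_group in uniq else uniq[0]
    g1 = [g for g in uniq if g != g0][0]
    i0, i1 = labels == g0, labels == g1
    n0, n1 = int(i0.sum()), int(i1.sum())
    if n0 < 2 or n1 < 2 or n0 + n1 < 4:
        raise ValueError("need >= 2 samples per group and >= 4 total")
    x = log_expr.to_numpy(dtype=float)
    m0 = x[:, i0].mean(axis=1)
    m1 = x[:, i1].mean(axis=1)
    log2fc = m1 - m0
    df_resid = n0 + n1 - 2
    ss = ((x[:, i0] - m0[:, None]) ** 2).sum(axis=1) + (
        (x[:, i1] - m1[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_f_dist(s2, df_resid)
    else:
        d0, s0_sq = fit_f_dist(s2, df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    v = 1.0 / n0 + 1.0 / n1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / np.sqrt(s2_post * v)
    t_mod = np.where(np.isfinite(t_mod), t_mod, 0.0)
    if math.isinf(df_total):
        pvalue = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        pvalue = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "t_mod": t_mod,
            "df_total": df_total,
            "pvalue": pvalue,
            "d0": d0,
            "s0_sq": s0_sq,
        },
        index=log_expr.index,
    )


# ---------------------------------------------------------------------------
# Organ calls and the cross-organ intersection
# ---------------------------------------------------------------------------


def organ_de(
    counts: CountMatrix, params: OrganDEParams | None = None, ref_group: str = "young"
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Call per-organ up/down genes at raw p and linear fold thresholds."""
    params = params or OrganDEParams()
    groups = counts.groups()
    if groups.nunique() < 2:
        raise ValueError("organ is missing a group")
    expr = logcpm(counts.counts, params.prior_count, params.cpm_floor)
    res = moderated_ttest(expr, groups.loc[expr.columns], ref_group=ref_group)
    lfc_cut = math.log2(params.fold_threshold)
    sig = res["pvalue"] < params.p_threshold
    up = set(res.index[sig & (res["log2fc"] > lfc_cut)])
    down = set(res.index[sig & (res["log2fc"] < -lfc_cut)])
    return up, down, res


def cross_organ_intersect(
    organ_up: dict[str, set[str]],
    candidates: set[str],
    min_organs: int | None = None,
) -> list[CrossOrganHit]:
    """Rank candidate genes by the number of organs calling them up.

    The reporting floor defaults to ceil(2/3 * n_organs); hits are sorted by
    organ count descending, then gene symbol.  Only genes at or above the
    floor are returned.
    """
    if len(organ_up) < 2:
        raise ValueError("need >= 2 organs")
    if not candidates:
        raise ValueError("empty candidate list")
    if min_organs is None:
        min_organs = math.ceil(2.0 * len(organ_up) / 3.0)
    hits = []
    for gene in sorted(candidates):
        organs = sorted(o for o, ups in organ_up.items() if gene in ups)
        if len(organs) >= min_organs:
            hits.append(CrossOrganHit(gene=gene, organs_up=organs))
    hits.sort(key=lambda h: (-h.n_organs_up, h.gene))
    return hits
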
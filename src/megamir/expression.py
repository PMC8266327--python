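"""Normalization, testing and classification of miRNA counts between age groups.

The differential test is a negative-binomial likelihood-ratio test with
tagwise method-of-moments dispersions shrunk toward the all-feature median.
Low-abundance features are removed by independent filtering: Benjamini-
Hochberg is applied on every mean-abundance quantile cut of a grid and the
cut maximizing the number of discoveries at the nominal FDR is kept (smallest
cut on ties).  Fold changes are reported as log2(old/young) of the fitted,
library-size-normalized group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix


@dataclass
class DEParams:
    alpha: float = 0.05
    min_change: float = 0.0  # minimum |fractional change| for up/down calls
    filter_quantiles: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 0.96, 0.01), 2)
    )
    dispersion_shrink: float = 0.9  # weight toward the common (median) dispersion

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        q = np.asarray(self.filter_quantiles, dtype=float)
        if (np.diff(q) < 0).any() or q.min() < 0 or q.max() >= 1:
            raise ValueError("filter_quantiles must be sorted within [0, 1)")
        if not 0 <= self.dispersion_shrink <= 1:
            raise ValueError("dispersion_shrink must be in [0, 1]")


@dataclass
class DistributionSummary:
    group: str
    median_rpm: float
    q1: float
    q3: float
    iqr: float
    upper_fence: float
    outlier_fraction: float


# ---------------------------------------------------------------------------
# Normalization and multiple testing
# ---------------------------------------------------------------------------


def rpm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Reads-per-million: each column rescaled to sum to 1e6."""
    totals = counts.counts.sum(axis=0)
    if (totals <= 0).any():
        zero = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total count: {zero}")
    return counts.counts / totals * 1e6


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Dispersion and the NB test
# ---------------------------------------------------------------------------


def _offsets(counts: pd.DataFrame) -> np.ndarray:
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    return lib / lib.mean()


def estimate_dispersion(
    counts: CountMatrix, groups: pd.Series | None = None, shrink: float = 0.9
) -> np.ndarray:
    """Per-feature NB dispersion phi (variance = mu + phi mu^2).

    Method of moments on within-group residuals around offset-scaled group
    means, with a small-sample correction (n/(n-1) per group), floored at 0,
    then shrunk linearly toward the all-feature median.
    """
    if groups is None:
        groups = counts.groups()
    y = counts.counts.to_numpy(dtype=float)
    s = _offsets(counts.counts)
    labels = np.asarray(groups)
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for g in np.unique(labels):
        idx = labels == g
        if idx.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sg = s[idx]
        yg = y[:, idx]
        m = yg.sum(axis=1) / sg.sum()  # Poisson-ish mean per offset unit
        mu = m[:, None] * sg[None, :]
        resid2 = (yg - mu) ** 2 * (idx.sum() / (idx.sum() - 1))
        num += (resid2 - mu).sum(axis=1)
        den += (mu**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    phi = np.maximum(phi, 0.0)
    common = float(np.median(phi))
    return (1 - shrink) * phi + shrink * common


def _nb_profile_loglik(
    y: np.ndarray, s: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Profile out the mean: returns (MLE mean per offset unit, loglik).

    Terms constant in the mean are dropped (they cancel in the LRT).
    y: features x samples; s: per-sample offsets; phi: per-feature.
    """
    tot = y.sum(axis=1)
    m = np.maximum(tot / s.sum(), 1e-12)  # Poisson MLE as the start
    poisson = phi <= 1e-12
    beta = np.log(m)
    ph = np.where(poisson, 1.0, phi)  # placeholder to keep vector math finite
    inv = 1.0 / ph
    for _ in range(60):
        mu = np.exp(beta)[:, None] * s[None, :]
        frac = ph[:, None] * mu / (1.0 + ph[:, None] * mu)
        grad = (y - (y + inv[:, None]) * frac).sum(axis=1)
        hess = ((y + inv[:, None]) * frac * (1.0 - frac)).sum(axis=1)
        step = np.where(hess > 0, grad / np.maximum(hess, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = beta + np.where(poisson, 0.0, step)
        if np.max(np.abs(step[~poisson] if (~poisson).any() else [0.0])) < 1e-10:
            break
    m_hat = np.where(poisson, m, np.exp(beta))
    mu = m_hat[:, None] * s[None, :]
    # y==0 terms: nb -> -(1/phi) log(1+phi mu); poisson -> -mu
    mu_safe = np.where(mu > 0, mu, 1.0)
    ll_nb = np.where(
        y > 0,
        y * np.log(mu_safe) - (y + inv[:, None]) * np.log1p(ph[:, None] * mu),
        -inv[:, None] * np.log1p(ph[:, None] * mu),
    )
    ll_po = np.where(y > 0, y * np.log(mu_safe) - mu, -mu)
    ll = np.where(poisson[:, None], ll_po, ll_nb).sum(axis=1)
    return m_hat, ll


def moderated_denominator_df(n_samples: int, shrink: float) -> float:
    """Denominator df for the LRT's F reference under shrunk dispersions.

    Shrinking tagwise dispersions with weight ``shrink`` toward the common
    value behaves like adding prior degrees of freedom to the residual
    df = n - 2, giving an effective df of (n - 2) / (1 - shrink); at full
    shrinkage the common dispersion is essentially noise-free and the
    reference reverts to chi-square(1) (df = inf).
    """
    d = n_samples - 2
    if shrink >= 1.0:
        return math.inf
    return d / (1.0 - shrink)


def nb_group_test(
    counts: CountMatrix,
    groups: pd.Series | None = None,
    phi: np.ndarray | None = None,
    ref_group: str = "young",
    offsets: np.ndarray | None = None,
    denom_df: float | None = None,
) -> pd.DataFrame:
    """NB likelihood-ratio test of a two-group mean difference per feature.

    Group means are fitted by profile likelihood with library-size offsets at
    fixed per-feature dispersion.  With ``denom_df=None`` the LRT statistic
    is referred to chi-square(1), which is calibrated when the dispersions
    are known; when they were estimated from the same data, pass a finite
    ``denom_df`` (see :func:`moderated_denominator_df`) to use an F(1, df)
    reference that absorbs the dispersion-estimation uncertainty.  Returns
    log2fc (non-reference over reference group), pvalue.  All-zero features
    get (0, 1) by convention.
    """
    if groups is None:
        groups = counts.groups()
    labels = np.asarray(groups)
    uniq = [g for g in pd.unique(labels)]
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    if ref_group in uniq:
        g0, g1 = ref_group, [g for g in uniq if g != ref_group][0]
    else:
        g0, g1 = uniq[0], uniq[1]
    if phi is None:
        phi = estimate_dispersion(counts, groups)
    phi = np.asarray(phi, dtype=float)
    y = counts.counts.to_numpy(dtype=float)
    s = _offsets(counts.counts) if offsets is None else np.asarray(offsets, float)
    i0 = labels == g0
    i1 = labels == g1

    m0, ll0 = _nb_profile_loglik(y[:, i0], s[i0], phi)
    m1, ll1 = _nb_profile_loglik(y[:, i1], s[i1], phi)
    _, ll_null = _nb_profile_loglik(y, s, phi)
    lrt = np.maximum(2.0 * (ll0 + ll1 - ll_null), 0.0)
    if denom_df is None or np.isinf(denom_df):
        pvalues = stats.chi2.sf(lrt, df=1)
    else:
        pvalues = stats.f.sf(lrt, 1, denom_df)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(m1 / m0)
    all_zero = y.sum(axis=1) == 0
    zero_one_side = (y[:, i0].sum(axis=1) == 0) ^ (y[:, i1].sum(axis=1) == 0)
    log2fc = np.where(all_zero, 0.0, log2fc)
    # one-sided zeros: keep the (finite) LRT p but clamp the infinite FC
    log2fc = np.where(zero_one_side & ~all_zero, np.sign(log2fc) * 30.0, log2fc)
    pvalues = np.where(all_zero, 1.0, pvalues)
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalues, "phi": phi},
        index=counts.counts.index,
    )


# ---------------------------------------------------------------------------
# Independent filtering and classification
# ---------------------------------------------------------------------------


def independent_filter(
    mean_rpm: np.ndarray, pvalues: np.ndarray, params: DEParams
) -> tuple[np.ndarray, float, np.ndarray]:
    """Pick the abundance cut maximizing BH discoveries at alpha.

    For each quantile theta of the grid, BH runs on features with mean RPM at
    or above that abundance quantile; the theta with the most rejections wins
    (smallest theta on ties).  Returns (kept mask, theta*, FDR array with NaN
    for filtered-out features).
    """
    mean_rpm = np.asarray(mean_rpm, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    if mean_rpm.shape != pvalues.shape:
        raise ValueError("mean_rpm and pvalues must align")
    best_theta, best_rej = None, -1
    for theta in np.asarray(params.filter_quantiles, dtype=float):
        cut = np.quantile(mean_rpm, theta)
        kept = mean_rpm >= cut
        if not kept.any():
            continue
        rej = int((benjamini_hochberg(pvalues[kept]) < params.alpha).sum())
        if rej > best_rej:
            best_theta, best_rej = float(theta), rej
    if best_theta is None:
        raise ValueError("empty kept set at every filter quantile")
    kept = mean_rpm >= np.quantile(mean_rpm, best_theta)
    fdr = np.full(pvalues.shape, np.nan)
    fdr[kept] = benjamini_hochberg(pvalues[kept])
    return kept, best_theta, fdr


def classify_features(de: pd.DataFrame, params: DEParams) -> pd.Series:
    """Assign down/steady/up/excluded from FDR, sign and minimum change."""
    cls = pd.Series("steady", index=de.index, dtype=object)
    excluded = de["fdr"].isna()
    cls[excluded] = "excluded"
    sig = ~excluded & (de["fdr"] < params.alpha)
    if params.min_change > 0:
        big = (2.0 ** de["log2fc"] - 1.0).abs() >= params.min_change
        sig = sig & big
    cls[sig & (de["log2fc"] < 0)] = "down"
    cls[sig & (de["log2fc"] > 0)] = "up"
    return cls


def run_de(
    counts: CountMatrix, params: DEParams | None = None, ref_group: str = "young"
) -> pd.DataFrame:
    """Full young-vs-old analysis: RPM, dispersion, NB LRT, filtering, classes."""
    params = params or DEParams()
    rpm = rpm_normalize(counts)
    groups = counts.groups()
    phi = estimate_dispersion(counts, groups, shrink=params.dispersion_shrink)
    ddf = moderated_denominator_df(len(counts.sample_ids), params.dispersion_shrink)
    test = nb_group_test(counts, groups, phi, ref_group=ref_group, denom_df=ddf)
    labels = np.asarray(groups)
    other = [g for g in pd.unique(labels) if g != ref_group][0]
    mean_young = rpm.loc[:, labels == ref_group].mean(axis=1)
    mean_old = rpm.loc[:, labels == other].mean(axis=1)
    mean_all = rpm.mean(axis=1)
    kept, theta, fdr = independent_filter(
        mean_all.to_numpy(), test["pvalue"].to_numpy(), params
    )
    out = pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "mean_rpm_young": mean_young.to_numpy(),
            "mean_rpm_old": mean_old.to_numpy(),
            "log2fc": test["log2fc"].to_numpy(),
            "pvalue": test["pvalue"].to_numpy(),
            "fdr": fdr,
        }
    ).set_index("feature_id")
    out["class"] = classify_features(out, params)
    out.attrs["filter_theta"] = theta
    return out


# ---------------------------------------------------------------------------
# Distribution summaries and sex stratification
# ---------------------------------------------------------------------------


def distribution_summary(rpm_values: np.ndarray, group: str = "") -> DistributionSummary:
    """Tukey box-plot summary: interpolated quartiles, q3 + 1.5 IQR fence."""
    v = np.asarray(rpm_values, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 values for a distribution summary")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    fence = q3 + 1.5 * iqr
    return DistributionSummary(
        group=group,
        median_rpm=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        upper_fence=float(fence),
        outlier_fraction=float((v > fence).mean()),
    )


def sex_stratified_flags(
    counts: CountMatrix, params: DEParams | None = None, ref_group: str = "young"
) -> pd.Series:
    """Flag features differentially expressed in exactly one sex.

    The NB test is re-run within each sex; a feature is flagged when its BH
    FDR is below alpha in one sex and not the other.  If a sex is missing
    from either group the flag is NA everywhere.
    """
    params = params or DEParams()
    meta = counts.sample_meta
    flags: dict[str, np.ndarray] = {}
    for sex in ("M", "F"):
        sel = meta["sex"] == sex
        sub_meta = meta[sel]
        if sub_meta["group"].nunique() < 2 or (sub_meta.groupby("group").size() < 2).any():
            return pd.Series(pd.NA, index=counts.counts.index, dtype=object)
        sub = CountMatrix(
            counts=counts.counts.loc[:, sel.index[sel]], sample_meta=sub_meta
        )
        phi = estimate_dispersion(sub, shrink=params.dispersion_shrink)
        ddf = moderated_denominator_df(len(sub.sample_ids), params.dispersion_shrink)
        test = nb_group_test(sub, phi=phi, ref_group=ref_group, denom_df=ddf)
        flags[sex] = benjamini_hochberg(test["pvalue"].to_numpy()) < params.alpha
    only_one = flags["M"] ^ flags["F"]
    return pd.Series(only_one, index=counts.counts.index)
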
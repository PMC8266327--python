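"""Hypergeometric pathway enrichment with kappa-score term grouping.

Each gene set is tested two-sided (enrichment or depletion, by doubling the
smaller exact hypergeometric tail), p-values are BH-corrected across all
tested terms, and the reporting filters (minimum genes per term, minimum %
of the term covered, adjusted alpha) are applied after correction.  Reported
terms are then grouped by pairwise Cohen's kappa between their binary
gene-membership vectors: iterating by ascending adjusted p, each ungrouped
term seeds a group and absorbs every later ungrouped term with kappa at or
above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichParams:
    min_genes_per_term: int = 4
    min_pct_per_term: float = 5.0  # percent of the term covered by the query
    kappa_threshold: float = 0.4
    adj_alpha: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.kappa_threshold < 1:
            raise ValueError("kappa_threshold must be in (0, 1)")
        if self.min_genes_per_term < 1 or self.min_pct_per_term < 0:
            raise ValueError("term filters must be positive")


def hypergeom_two_sided(k: int, N: int, K: int, n: int) -> float:
    """Two-sided hypergeometric p: double the smaller exact tail, cap at 1."""
    upper = stats.hypergeom.sf(k - 1, N, K, n)
    lower = stats.hypergeom.cdf(k, N, K, n)
    return float(min(1.0, 2.0 * min(upper, lower)))


def hypergeometric_enrichment(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    params: EnrichParams | None = None,
) -> pd.DataFrame:
    """Test every gene set for over/under-representation of the query.

    Terms are intersected with the universe before testing; the returned
    frame has one row per tested term with k, K, n, N, pct, p_two_sided,
    p_adj and a ``reported`` flag for terms passing the post-correction
    filters.  Hit genes per term are kept in the ``hits`` column.
    """
    params = params or EnrichParams()
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in sorted(gene_sets.items()):
        members = genes & universe
        if not members:
            continue
        hits = members & query
        k, K = len(hits), len(members)
        rows.append(
            {
                "term_id": term,
                "term_name": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pct": 100.0 * k / K,
                "p_two_sided": hypergeom_two_sided(k, N, K, n),
                "hits": frozenset(hits),
            }
        )
    if not rows:
        raise ValueError("no term overlaps the universe")
    df = pd.DataFrame(rows)
    # BH across tested terms (own step-up; shared with the DE stage)
    from .expression import benjamini_hochberg

    df["p_adj"] = benjamini_hochberg(df["p_two_sided"].to_numpy())
    df["reported"] = (
        (df["k"] >= params.min_genes_per_term)
        & (df["pct"] >= params.min_pct_per_term)
        & (df["p_adj"] < params.adj_alpha)
    )
    return df.set_index("term_id")


def cohen_kappa(set_a: set[str], set_b: set[str], universe: set[str]) -> float:
    """Cohen's kappa between two binary gene memberships over a universe."""
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    a = set_a & universe
    b = set_b & universe
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = N - both - only_a - only_b
    po = (both + neither) / N
    pa, pb = len(a) / N, len(b) / N
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def kappa_group_terms(
    enrich: pd.DataFrame,
    universe: set[str],
    kappa_threshold: float = 0.4,
) -> pd.DataFrame:
    """Group reported terms by kappa agreement of their hit-gene sets.

    Terms are visited by ascending adjusted p (term id breaks ties); an
    ungrouped term becomes the leader of a new group and every remaining
    ungrouped term with kappa >= threshold against the leader joins it.
    Returns the reported rows with ``group_id`` and ``is_group_leader``.
    """
    rep = enrich[enrich["reported"]].copy()
    if rep.empty:
        rep["group_id"] = pd.Series(dtype=int)
        rep["is_group_leader"] = pd.Series(dtype=bool)
        return rep
    order = rep.sort_values(["p_adj", "term_name"]).index.tolist()
    group_of: dict[str, int] = {}
    leaders: list[str] = []
    for term in order:
        if term in group_of:
            continue
        gid = len(leaders)
        leaders.append(term)
        group_of[term] = gid
        lead_hits = set(rep.loc[term, "hits"])
        for other in order:
            if other in group_of:
                continue
            kappa = cohen_kappa(lead_hits, set(rep.loc[other, "hits"]), universe)
            if kappa >= kappa_threshold:
                group_of[other] = gid
    rep["group_id"] = [group_of[t] for t in rep.index]
    rep["is_group_leader"] = [t in leaders for t in rep.index]
    return rep


def reported_genes(enrich: pd.DataFrame) -> set[str]:
    """Union of query hit genes across all reported terms."""
    out: set[str] = set()
    for hits in enrich.loc[enrich["reported"], "hits"]:
        out |= set(hits)
    return out
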
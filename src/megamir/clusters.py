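"""Genomic mapping of classified miRNAs: per-chromosome frequencies, max-gap
cluster detection, dominant-strand collapse and a locus-coordination test.

The genomic position of a mature miRNA is the first transcribed base of its
mature sequence: the interval start on the + strand, the interval end on the
- strand.  Cluster detection chains gene-level positions: consecutive genes
(sorted by position) whose spacing is at most ``max_gap`` belong to one
chain, and maximal chains of at least ``min_size`` genes are clusters.
Coordination within a cluster is scored by an exact two-sided sign
(binomial) test on the member genes' fold-change signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import MirnaAnnotation

DEFAULT_MAX_GAP = 10_000
DEFAULT_MIN_SIZE = 5


@dataclass(frozen=True)
class GenomicPosition:
    mature_id: str
    chrom: str
    pos: int
    strand: str
    multi_locus: bool = False


@dataclass
class Cluster:
    cluster_id: str
    chrom: str
    start: int
    end: int
    member_genes: list[str]
    n_mature: int = 0
    composition: dict[str, int] = field(default_factory=dict)
    n_negative_fc: int | None = None
    n_members_tested: int | None = None
    binomial_p: float | None = None

    @property
    def span_bp(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Positions and chromosome frequencies
# ---------------------------------------------------------------------------


def assign_positions(
    annotation: MirnaAnnotation, mature_ids: list[str]
) -> tuple[list[GenomicPosition], list[str]]:
    """Map analyzed mature ids to 5'-end genomic positions.

    Returns (positions, unmapped ids).  A mature name carried by arms of more
    than one gene is flagged ``multi_locus`` (its chromosome is ambiguous).
    """
    by_name: dict[str, list] = {}
    for m in annotation.matures.values():
        by_name.setdefault(m.mature_id, []).append(m)
        if m.name != m.mature_id:
            by_name.setdefault(m.name, []).append(m)
    positions, unmapped = [], []
    for mid in mature_ids:
        hits = by_name.get(mid, [])
        if not hits:
            unmapped.append(mid)
            continue
        parents = {h.parent_gene for h in hits}
        m = hits[0]
        pos = m.start if m.strand == "+" else m.end
        positions.append(
            GenomicPosition(
                mature_id=mid, chrom=m.chrom, pos=pos, strand=m.strand,
                multi_locus=len(parents) > 1,
            )
        )
    return positions, unmapped


def chromosome_frequency(
    positions: list[GenomicPosition], classes: dict[str, str]
) -> pd.DataFrame:
    """Tabulate down/steady/up counts per chromosome plus a 'multiple' row."""
    rows: dict[str, dict[str, int]] = {}
    for p in positions:
        if p.mature_id not in classes:
            raise ValueError(f"no class for {p.mature_id}")
        key = "multiple" if p.multi_locus else p.chrom
        row = rows.setdefault(key, {"n_down": 0, "n_steady": 0, "n_up": 0})
        cls = classes[p.mature_id]
        row[f"n_{cls}"] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    for col in ("n_down", "n_steady", "n_up"):
        if col not in table.columns:
            table[col] = 0
    table = table[["n_down", "n_steady", "n_up"]]
    table["n_total"] = table.sum(axis=1)
    return table.sort_index()


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------


def detect_clusters(
    gene_positions: dict[str, tuple[str, int]],
    max_gap: int = DEFAULT_MAX_GAP,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[Cluster]:
    """Greedy max-gap chaining of gene positions into maximal clusters.

    ``gene_positions`` maps gene_id -> (chrom, position).  Genes are sorted
    by position within each chromosome; consecutive genes with spacing
    <= max_gap join one chain, chains with >= min_size genes are reported.
    Maximality holds by construction: the gene before a chain's first and
    after its last (if any) are farther than max_gap.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gid, (chrom, pos) in gene_positions.items():
        by_chrom.setdefault(chrom, []).append((pos, gid))
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom])
        chain = [items[0]]
        for prev, cur in zip(items, items[1:]):
            if cur[0] - prev[0] <= max_gap:
                chain.append(cur)
            else:
                if len(chain) >= min_size:
                    clusters.append(_make_cluster(chrom, chain, len(clusters)))
                chain = [cur]
        if len(chain) >= min_size:
            clusters.append(_make_cluster(chrom, chain, len(clusters)))
    return clusters


def _make_cluster(chrom: str, chain: list[tuple[int, str]], idx: int) -> Cluster:
    return Cluster(
        cluster_id=f"cluster_{idx + 1}",
        chrom=chrom,
        start=chain[0][0],
        end=chain[-1][0],
        member_genes=[gid for _, gid in chain],
    )


# ---------------------------------------------------------------------------
# Dominant-strand collapse
# ---------------------------------------------------------------------------


def dominant_strand(arm_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse -3p/-5p arms to one representative arm per gene.

    Expects columns gene_id, arm, mean_rpm_young and optionally
    mean_rpm_old and class.  The representative arm is the one with the
    greater young-group mean RPM; on an exact tie the -5p arm is chosen.
    The gene inherits the representative arm's class.
    """
    required = {"gene_id", "arm", "mean_rpm_young"}
    if not required <= set(arm_table.columns):
        raise ValueError(f"need columns {sorted(required)}")
    rows = []
    for gene_id, grp in arm_table.groupby("gene_id", sort=True):
        if grp.empty:
            continue
        # sort so that on an expression tie the 5p arm wins
        grp = grp.sort_values(
            ["mean_rpm_young", "arm"], ascending=[False, False], kind="mergesort"
        )
        top = grp.iloc[0]
        row = {
            "gene_id": gene_id,
            "representative_arm": top["arm"],
            "representative_rpm_young": float(top["mean_rpm_young"]),
        }
        if "mean_rpm_old" in grp.columns:
            row["representative_rpm_old"] = float(top["mean_rpm_old"])
        if "class" in grp.columns:
            row["gene_class"] = top["class"]
        if "log2fc" in grp.columns:
            row["log2fc"] = float(top["log2fc"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def load_strand_expression_fixture() -> pd.DataFrame:
    """Bundled strand-level young-group mean RPM table (both-arm miRNA genes
    of the mega-cluster, as measured in young cardiac fibroblasts)."""
    path = resources.files("megamir.data") / "strand_expression.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# Locus coordination
# ---------------------------------------------------------------------------


def locus_coordination(
    cluster: Cluster, gene_log2fc: dict[str, float], min_members: int = 5
) -> Cluster:
    """Exact two-sided sign test of coordinated repression within a cluster.

    Members with finite, non-zero gene-level log2fc are counted; the number
    with negative sign is referred to Binomial(n, 0.5).  Fewer than
    ``min_members`` usable members leaves the statistic as None.
    """
    fcs = [
        gene_log2fc[g]
        for g in cluster.member_genes
        if g in gene_log2fc and np.isfinite(gene_log2fc[g]) and gene_log2fc[g] != 0
    ]
    if len(fcs) < min_members:
        cluster.n_negative_fc = None
        cluster.n_members_tested = None
        cluster.binomial_p = None
        return cluster
    n_neg = sum(1 for f in fcs if f < 0)
    cluster.n_negative_fc = n_neg
    cluster.n_members_tested = len(fcs)
    cluster.binomial_p = float(
        stats.binomtest(n_neg, len(fcs), 0.5, alternative="two-sided").pvalue
    )
    return cluster
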
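"""Consensus target prediction across sources and canonical seed-site counting.

A miRNA-gene pair is a consensus target when it is predicted by at least
``min_sources`` distinct sources (default 2 of 3).  Seed sites in a 3'UTR are
the canonical classes: the seed is miRNA nucleotides 2-8, a site is a
Watson-Crick reverse-complement match in the UTR, and each matched position
is reported once under its strongest class
(8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A", "T": "A"}


@dataclass
class ConsensusTargets:
    """mirna -> consensus gene symbols, with per-pair source support."""

    pairs: pd.DataFrame  # columns mirna_id, gene_symbol, support

    def targets_of(self, mirna_id: str) -> set[str]:
        sel = self.pairs["mirna_id"] == mirna_id
        return set(self.pairs.loc[sel, "gene_symbol"])

    def all_genes(self) -> set[str]:
        return set(self.pairs["gene_symbol"])


@dataclass
class SeedMatchReport:
    mirna_id: str
    utr_id: str
    counts: dict[str, int] = field(default_factory=dict)
    positions: dict[str, list[int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def consensus_targets(
    tables: list[pd.DataFrame], min_sources: int = 2
) -> ConsensusTargets:
    """Keep pairs predicted by >= min_sources distinct sources.

    Each table carries columns source, mirna_id, gene_symbol (the
    read_target_table layout).  Gene symbols are matched case-insensitively
    after trimming; duplicates within a source count once.
    """
    if not tables:
        raise ValueError("no prediction tables supplied")
    df = pd.concat(tables, ignore_index=True)
    n_sources = df["source"].nunique()
    if min_sources > n_sources:
        raise ValueError(f"min_sources={min_sources} exceeds {n_sources} sources")
    df = df.assign(
        gene_key=df["gene_symbol"].astype(str).str.strip().str.upper(),
        mirna_id=df["mirna_id"].astype(str).str.strip(),
    )
    dedup = df.drop_duplicates(["source", "mirna_id", "gene_key"])
    support = (
        dedup.groupby(["mirna_id", "gene_key"])["source"].nunique().rename("support")
    )
    symbol = dedup.groupby(["mirna_id", "gene_key"])["gene_symbol"].first()
    out = pd.concat([symbol, support], axis=1).reset_index()
    out = out[out["support"] >= min_sources]
    out = out[["mirna_id", "gene_symbol", "support"]].sort_values(
        ["mirna_id", "gene_symbol"], ignore_index=True
    )
    return ConsensusTargets(pairs=out)


def _clean_seq(seq: str, label: str) -> str:
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"{label}: non-ACGU/ACGT characters {sorted(bad)}")
    return s


def count_seed_sites(
    mirna_seq: str, utr_seq: str, mirna_id: str = "", utr_id: str = ""
) -> SeedMatchReport:
    """Count canonical seed-match sites of a miRNA in a 3'UTR.

    Scans for reverse-complement matches of the miRNA seed (nt 2-7 core);
    each core match is classified by whether nt 8 also pairs (m8) and
    whether the UTR base opposite miRNA nt 1 is an A (A1):
    both -> 8mer, m8 only -> 7mer-m8, A1 only -> 7mer-A1, neither -> 6mer.
    Positions are 1-based starts of the 6mer core in the UTR.
    """
    mir = _clean_seq(mirna_seq, "miRNA")
    utr = _clean_seq(utr_seq, "UTR")
    if len(mir) < 8:
        raise ValueError("miRNA must be >= 8 nt")
    if len(utr) < 7:
        raise ValueError("UTR must be >= 7 nt")
    # reverse complement of seed nt 2-7, written 5'->3' in UTR space
    core = "".join(_COMPLEMENT[b] for b in reversed(mir[1:7]))
    m8_base = _COMPLEMENT[mir[7]]  # pairs miRNA nt 8, sits 5' of the core in the UTR
    counts = {t: 0 for t in SITE_TYPES}
    positions: dict[str, list[int]] = {t: [] for t in SITE_TYPES}
    for j in range(len(utr) - 5):
        if utr[j : j + 6] != core:
            continue
        has_m8 = j >= 1 and utr[j - 1] == m8_base
        has_a1 = j + 6 < len(utr) and utr[j + 6] == "A"
        if has_m8 and has_a1:
            site = "8mer"
        elif has_m8:
            site = "7mer-m8"
        elif has_a1:
            site = "7mer-A1"
        else:
            site = "6mer"
        counts[site] += 1
        positions[site].append(j + 1)
    return SeedMatchReport(
        mirna_id=mirna_id, utr_id=utr_id, counts=counts, positions=positions
    )
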
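"""Readers and writers for the tabular and genomic formats the pipeline touches.

Internal coordinates are GFF3-style: 1-based, inclusive on both ends.  The
single place where that convention is converted is :func:`write_bed` (BED is
0-based, half-open).  Readers validate strictly and raise :class:`FormatError`
rather than coercing bad values.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = {"young", "old", "very_old", "custom"}
VALID_SEXES = {"M", "F", "NA"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MirnaGene:
    """A miRNA gene (primary transcript) on the genome.

    Coordinates are 1-based inclusive; ``strand`` is '+' or '-'.
    """

    gene_id: str
    name: str
    chrom: str
    strand: str
    start: int
    end: int
    locus_label: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA arm, linked to its parent gene.

    ``arm`` is '3p', '5p' or 'unspecified' (parsed from the name suffix).
    """

    mature_id: str
    name: str
    arm: str
    parent_gene: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in {"3p", "5p", "unspecified"}:
            raise FormatError(f"{self.mature_id}: bad arm {self.arm!r}")
        if self.start > self.end:
            raise FormatError(f"{self.mature_id}: start > end")


@dataclass
class MirnaAnnotation:
    """Container for miRNA genes and their mature arms."""

    genes: dict[str, MirnaGene] = field(default_factory=dict)
    matures: dict[str, MatureMirna] = field(default_factory=dict)

    def add_gene(self, gene: MirnaGene) -> None:
        if gene.gene_id in self.genes:
            raise FormatError(f"duplicate gene id {gene.gene_id}")
        self.genes[gene.gene_id] = gene

    def add_mature(self, mature: MatureMirna, slack: int = 10) -> None:
        if mature.parent_gene not in self.genes:
            raise FormatError(f"mature {mature.mature_id}: unknown parent {mature.parent_gene}")
        parent = self.genes[mature.parent_gene]
        if mature.start < parent.start - slack or mature.end > parent.end + slack:
            raise FormatError(
                f"mature {mature.mature_id} [{mature.start},{mature.end}] outside parent "
                f"{parent.gene_id} [{parent.start},{parent.end}] (slack {slack})"
            )
        if mature.mature_id in self.matures:
            raise FormatError(f"duplicate mature id {mature.mature_id}")
        self.matures[mature.mature_id] = mature

    def arms_of(self, gene_id: str) -> list[MatureMirna]:
        return [m for m in self.matures.values() if m.parent_gene == gene_id]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with per-sample metadata.

    ``counts`` has feature ids as the index and sample ids as columns;
    ``sample_meta`` is indexed by sample id with columns ``group``, ``sex``
    and ``organ``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise FormatError("duplicate feature ids")
        if c.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        arr = c.to_numpy()
        if arr.size and not ((arr >= 0).all() and (arr == arr.astype(int)).all()):
            bad = (arr < 0) | (arr != arr.astype(int))
            i, j = [x[0] for x in bad.nonzero()]
            raise FormatError(
                f"counts must be non-negative integers; offending entry at "
                f"feature {c.index[i]!r}, sample {c.columns[j]!r} = {arr[i, j]}"
            )
        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise FormatError(f"samples missing from metadata: {sorted(missing)}")
        if "group" not in self.sample_meta.columns:
            raise FormatError("sample metadata must have a 'group' column")
        bad_groups = set(self.sample_meta["group"]) - VALID_GROUPS
        if bad_groups:
            raise FormatError(f"unknown groups: {sorted(bad_groups)}")
        self.counts = c.astype(int)
        self.sample_meta = self.sample_meta.loc[list(c.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def groups(self) -> pd.Series:
        return self.sample_meta["group"]


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def write_counts(cm: CountMatrix, path: str, meta_path: str) -> None:
    df = cm.counts.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")
    meta = cm.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def read_counts(path: str, meta_path: str) -> CountMatrix:
    """Read a counts TSV (features x samples) plus a sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count entry ({exc})") from exc
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    for col in ("sex", "organ"):
        if col not in meta.columns:
            meta[col] = "NA"
    meta = meta.fillna("NA")
    return CountMatrix(counts=df, sample_meta=meta)


# ---------------------------------------------------------------------------
# miRNA GFF3 (miRBase dialect)
# ---------------------------------------------------------------------------


def _arm_from_name(name: str) -> str:
    low = name.lower()
    if low.endswith("-3p"):
        return "3p"
    if low.endswith("-5p"):
        return "5p"
    return "unspecified"


def write_mirna_gff(ann: MirnaAnnotation, path: str) -> None:
    """Write the annotation as miRBase-dialect GFF3 (deterministic order)."""
    lines = ["##gff-version 3"]
    for gid in sorted(ann.genes):
        g = ann.genes[gid]
        attrs = f"ID={g.gene_id};Name={g.name}"
        if g.locus_label:
            attrs += f";locus={g.locus_label}"
        lines.append(
            f"{g.chrom}\tmegamir\tmiRNA_primary_transcript\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for m in sorted(ann.arms_of(gid), key=lambda m: m.mature_id):
            lines.append(
                f"{m.chrom}\tmegamir\tmiRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.mature_id};Name={m.name};Derives_from={g.gene_id}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mirna_gff(path: str) -> MirnaAnnotation:
    """Parse a miRBase-dialect GFF3 into a :class:`MirnaAnnotation`.

    Feature types ``miRNA_primary_transcript`` (genes) and ``miRNA`` (arms,
    linked via ``Derives_from``).  Arm laterality comes from the -3p/-5p name
    suffix; anything else is 'unspecified' (warning logged).
    """
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    ann = MirnaAnnotation()
    for feat in db.features_of_type("miRNA_primary_transcript"):
        if feat.start is None or feat.end is None:
            raise FormatError(f"malformed coordinates for {feat.id}")
        ann.add_gene(
            MirnaGene(
                gene_id=feat.id,
                name=feat.attributes.get("Name", [feat.id])[0],
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                locus_label=feat.attributes.get("locus", [None])[0],
            )
        )
    for feat in db.features_of_type("miRNA"):
        parents = feat.attributes.get("Derives_from", [])
        if not parents or parents[0] not in ann.genes:
            raise FormatError(f"orphan mature miRNA {feat.id} (no Derives_from parent)")
        name = feat.attributes.get("Name", [feat.id])[0]
        arm = _arm_from_name(name)
        if arm == "unspecified":
            logger.warning("mature miRNA %s has no -3p/-5p suffix; arm=unspecified", name)
        ann.add_mature(
            MatureMirna(
                mature_id=feat.id,
                name=name,
                arm=arm,
                parent_gene=parents[0],
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
        )
    return ann


# ---------------------------------------------------------------------------
# Gene sets (GMT), target-prediction tables, Ct tables, BED
# ---------------------------------------------------------------------------


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT file into {term_name: gene set}."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, desc, >=1 gene")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = set(genes)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str, desc: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, desc] + sorted(sets[name])) + "\n")


def read_target_table(
    path: str, source_name: str, score_min: float | None = None
) -> pd.DataFrame:
    """Read a miRNA->gene prediction TSV (columns mirna, gene[, score]).

    Rows with a score below ``score_min`` are dropped (rows without a score
    are kept).  Returns columns source, mirna_id, gene_symbol, score.
    """
    df = pd.read_csv(path, sep="\t")
    known = {"mirna", "gene", "score"}
    unknown = set(df.columns) - known
    if unknown:
        raise FormatError(f"{path}: unknown columns {sorted(unknown)}")
    if not {"mirna", "gene"} <= set(df.columns):
        raise FormatError(f"{path}: need 'mirna' and 'gene' columns")
    if "score" not in df.columns:
        df["score"] = float("nan")
    if score_min is not None:
        df = df[df["score"].isna() | (df["score"] >= score_min)]
    out = pd.DataFrame(
        {
            "source": source_name,
            "mirna_id": df["mirna"].astype(str),
            "gene_symbol": df["gene"].astype(str),
            "score": df["score"].astype(float),
        }
    )
    return out.reset_index(drop=True)


def write_target_table(df: pd.DataFrame, path: str) -> None:
    out = df.rename(columns={"mirna_id": "mirna", "gene_symbol": "gene"})
    out[["mirna", "gene", "score"]].to_csv(path, sep="\t", index=False)


def read_ct_table(path: str) -> pd.DataFrame:
    """Read a qPCR Ct TSV; validates the 0 < Ct < 45 cycle range."""
    df = pd.read_csv(path, sep="\t")
    required = {
        "sample_id", "group", "organ_or_celltype", "target_assay",
        "ct_target", "reference_assay", "ct_reference",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing Ct columns {sorted(missing)}")
    for col in ("ct_target", "ct_reference"):
        vals = df[col].astype(float)
        if ((vals <= 0) | (vals >= 45)).any():
            raise FormatError(f"{path}: {col} outside (0, 45)")
        df[col] = vals
    return df


def write_ct_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(clusters, path: str) -> None:
    """Export clusters as BED6 (0-based half-open; score = member count)."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(
                f"{cl.chrom}\t{cl.start - 1}\t{cl.end}\t{cl.cluster_id}\t"
                f"{len(cl.member_genes)}\t+\n"
            )


def gff_roundtrip_equal(ann_a: MirnaAnnotation, ann_b: MirnaAnnotation) -> bool:
    return ann_a.genes == ann_b.genes and ann_a.matures == ann_b.matures
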
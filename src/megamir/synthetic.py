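"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-age-group small-RNA-seq design (negative-binomial
counts, n per group with balanced sexes), a genomic mega-cluster of miRNA genes
carrying a coordinated repression in the old group, -3p/-5p arm asymmetry,
multi-organ bulk count matrices with planted aged-upregulated genes, three
overlapping target-prediction sources with a known consensus set, pathway gene
sets, and comparative-CT qPCR tables.  Every planted effect is recorded in a
truth table so each downstream stage can be checked against ground truth.

All outputs are pure functions of :class:`SimulationConfig` (seed included):
the same config yields bit-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import CountMatrix, MatureMirna, MirnaAnnotation, MirnaGene

GENE_LEN = 80  # toy pri-miRNA length, bp
ARM_LEN = 22
MIN_OFFCLUSTER_GAP = 15_000  # keeps background genes out of default cluster calls


@dataclass
class ClusterSpec:
    """Where the planted mega-cluster lives and how densely it is packed."""

    chrom: str = "chr12"
    start: int = 1_000_000
    n_genes: int = 50
    gap: int = 2_000  # end-to-start spacing between consecutive genes, bp


@dataclass
class OrganSpec:
    """Multi-organ bulk RNA-seq emulation with planted aged-up genes."""

    organs: tuple[str, ...] = ("organ1", "organ2", "organ3", "organ4", "organ5", "organ6")
    n_genes: int = 2_000
    n_samples_per_group: int = 5
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    target_depth: float = 1e6
    # gene -> (organs in which it is planted up, linear fold change old/young)
    planted: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: {
            "gene0001": (("organ1", "organ2", "organ3", "organ4"), 2.0),
            "gene0002": (("organ1", "organ5"), 2.0),
            "gene0003": (("organ6",), 2.0),
        }
    )


@dataclass
class TargetDbSpec:
    """Three overlapping prediction sources plus pathway gene sets."""

    sources: tuple[str, ...] = ("targetscan", "mirdb", "diana")
    n_universe: int = 500
    n_planted: int = 30  # consensus pairs (each in >=2 sources)
    n_decoys: int = 60  # single-source pairs
    n_mirnas: int = 27  # distinct cluster miRNAs used as query ids
    n_terms: int = 10  # random pathway terms
    term_size: int = 40
    true_term_consensus: int = 25  # consensus genes packed into the true term


@dataclass
class QpcrSpec:
    """Comparative-CT measurement model: Ct = base - log2(expression) + noise."""

    assays: tuple[str, ...] = ("mir-cl-1", "mir-cl-2", "mir-cl-3", "mir-cl-4")
    reference_assay: str = "U6"
    groups: tuple[str, ...] = ("young", "old", "very_old")
    # delta-Ct shift per group relative to young (positive = repressed)
    shifts: dict[str, float] = field(
        default_factory=lambda: {"young": 0.0, "old": 0.515, "very_old": 1.322}
    )
    n_per_group: int = 10
    noise_sd: float = 0.3
    base_ct: float = 25.0
    reference_ct: float = 18.0
    context: str = "cardiac_fibroblast"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 130_000_000
    n_mirna_genes: int = 300
    cluster_spec: ClusterSpec = field(default_factory=ClusterSpec)
    n_samples_per_group: int = 6
    sex_balance: float = 0.5
    baseline_mean: float = 200.0
    expression_sigma: float = 1.2  # log-normal spread of per-gene baseline means
    dispersion: float = 0.05  # NB phi, variance = mu + phi mu^2
    target_depth: float = 1e6
    # scalar old/young ratio, or (low, high) for a per-gene uniform sampler
    locus_effect: float | tuple[float, float] = 0.6
    frac_cluster_affected: float = 0.6
    arm_ratio: float = 30.0
    organ_spec: OrganSpec = field(default_factory=OrganSpec)
    targetdb_spec: TargetDbSpec = field(default_factory=TargetDbSpec)
    qpcr_spec: QpcrSpec = field(default_factory=QpcrSpec)

    def validate(self) -> None:
        cs = self.cluster_spec
        if self.n_mirna_genes < cs.n_genes:
            raise ValueError("n_mirna_genes must be >= cluster n_genes")
        span = cs.n_genes * GENE_LEN + (cs.n_genes - 1) * cs.gap
        if cs.start + span > self.chrom_length:
            raise ValueError("cluster span exceeds chromosome length")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.n_samples_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        lo, hi = self._effect_range()
        if lo <= 0 or hi <= 0:
            raise ValueError("locus_effect must be positive")
        if self.qpcr_spec.noise_sd < 0:
            raise ValueError("qPCR noise SD must be >= 0")
        for gene, (organs, fold) in self.organ_spec.planted.items():
            if fold <= 1:
                raise ValueError(f"planted up-gene {gene} needs fold > 1, got {fold}")

    def _effect_range(self) -> tuple[float, float]:
        if isinstance(self.locus_effect, (tuple, list)):
            lo, hi = self.locus_effect
            return float(lo), float(hi)
        return float(self.locus_effect), float(self.locus_effect)

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["organ_spec"]["planted"] = {
            g: {"organs": list(o), "fold": f}
            for g, (o, f) in self.organ_spec.planted.items()
        }
        if isinstance(self.locus_effect, (tuple, list)):
            d["locus_effect"] = list(self.locus_effect)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cluster_spec" in d:
            d["cluster_spec"] = ClusterSpec(**d["cluster_spec"])
        if "organ_spec" in d:
            od = dict(d["organ_spec"])
            if "planted" in od:
                od["planted"] = {
                    g: (tuple(v["organs"]), float(v["fold"]))
                    for g, v in od["planted"].items()
                }
            if "organs" in od:
                od["organs"] = tuple(od["organs"])
            d["organ_spec"] = OrganSpec(**od)
        if "targetdb_spec" in d:
            td = dict(d["targetdb_spec"])
            if "sources" in td:
                td["sources"] = tuple(td["sources"])
            d["targetdb_spec"] = TargetDbSpec(**td)
        if "qpcr_spec" in d:
            qd = dict(d["qpcr_spec"])
            for k in ("assays", "groups"):
                if k in qd:
                    qd[k] = tuple(qd[k])
            d["qpcr_spec"] = QpcrSpec(**qd)
        if isinstance(d.get("locus_effect"), list):
            d["locus_effect"] = tuple(d["locus_effect"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per operation
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def simulate_annotation(config: SimulationConfig) -> MirnaAnnotation:
    """Place a dense mega-cluster on one chromosome and scatter the rest.

    Cluster genes are consecutive with the configured end-to-start gap;
    background genes go to the other chromosomes with start-to-start spacing
    well above the default cluster-detection gap so they never chain.
    """
    config.validate()
    rng = _rng(config, 1)
    cs = config.cluster_spec
    other_chroms = [f"chr{i}" for i in range(1, config.n_chromosomes)]
    if cs.chrom in other_chroms:
        other_chroms.remove(cs.chrom)

    ann = MirnaAnnotation()
    width = len(str(config.n_mirna_genes))

    def add(idx: int, chrom: str, start: int, strand: str, locus: str | None) -> None:
        gid = f"mirg-{idx:0{width}d}"
        gene = MirnaGene(
            gene_id=gid, name=gid, chrom=chrom, strand=strand,
            start=start, end=start + GENE_LEN - 1, locus_label=locus,
        )
        ann.add_gene(gene)
        for arm, a_start in (("5p", start), ("3p", start + GENE_LEN - ARM_LEN)):
            ann.add_mature(
                MatureMirna(
                    mature_id=f"{gid}-{arm}", name=f"{gid}-{arm}", arm=arm,
                    parent_gene=gid, chrom=chrom, strand=strand,
                    start=a_start, end=a_start + ARM_LEN - 1,
                )
            )

    pos = cs.start
    for i in range(cs.n_genes):
        add(i + 1, cs.chrom, pos, "+", "megacluster")
        pos += GENE_LEN + cs.gap

    n_rest = config.n_mirna_genes - cs.n_genes
    if n_rest and not other_chroms:
        other_chroms = [cs.chrom]  # single-chromosome toy configs
    if n_rest:
        chrom_of = rng.integers(0, len(other_chroms), size=n_rest)
        idx = cs.n_genes + 1
        for c, chrom in enumerate(other_chroms):
            n_here = int((chrom_of == c).sum())
            gaps = rng.integers(MIN_OFFCLUSTER_GAP, 400_000, size=n_here)
            start = int(rng.integers(50_000, 200_000))
            for g in gaps:
                strand = "+" if rng.random() < 0.5 else "-"
                add(idx, chrom, start, strand, None)
                start += int(g) + GENE_LEN
                idx += 1
    return ann


# ---------------------------------------------------------------------------
# miRNA counts
# ---------------------------------------------------------------------------


def simulate_mirna_counts(
    annotation: MirnaAnnotation, config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Arm-level NB counts for young vs old with a planted locus repression.

    Each gene gets a log-normal baseline mean; one arm (picked at random) is
    dominant by ``arm_ratio``.  A fraction of cluster genes carries an old/young
    ratio drawn from ``locus_effect`` on both arms.  Returns the count matrix
    and a per-feature truth table (affected flag and true ratio).
    """
    config.validate()
    rng = _rng(config, 2)
    n = config.n_samples_per_group

    gene_ids = sorted(annotation.genes)
    cluster_genes = [g for g in gene_ids if annotation.genes[g].locus_label == "megacluster"]
    n_affected = int(round(config.frac_cluster_affected * len(cluster_genes)))
    affected = set(
        rng.choice(np.array(cluster_genes), size=n_affected, replace=False).tolist()
    ) if n_affected else set()
    lo, hi = config._effect_range()

    rows = []
    for gid in gene_ids:
        base = float(
            config.baseline_mean * np.exp(rng.normal(0.0, config.expression_sigma))
        )
        dominant = "5p" if rng.random() < 0.5 else "3p"
        is_affected = gid in affected
        ratio = float(rng.uniform(lo, hi)) if is_affected else 1.0
        for m in sorted(annotation.arms_of(gid), key=lambda m: m.mature_id):
            mu = base if m.arm == dominant else base / config.arm_ratio
            rows.append(
                {
                    "feature_id": m.mature_id,
                    "gene_id": gid,
                    "arm": m.arm,
                    "is_cluster": annotation.genes[gid].locus_label == "megacluster",
                    "affected": is_affected and ratio != 1.0,
                    "true_ratio": ratio,
                    "base_mean": mu,
                }
            )
    truth = pd.DataFrame(rows).set_index("feature_id")

    mu = truth["base_mean"].to_numpy()
    ratio = truth["true_ratio"].to_numpy()
    total = mu.sum()
    scale = config.target_depth / total
    sample_ids, groups, sexes, cols = [], [], [], []
    n_male = int(round(config.sex_balance * n))
    for group, prefix in (("young", "y"), ("old", "o")):
        for j in range(n):
            depth_factor = rng.uniform(0.8, 1.2)
            mean_vec = mu * scale * depth_factor
            if group == "old":
                mean_vec = mean_vec * ratio
            cols.append(_nb_draw(rng, mean_vec, config.dispersion))
            sample_ids.append(f"{prefix}{j + 1}")
            groups.append(group)
            sexes.append("M" if j < n_male else "F")
    counts = pd.DataFrame(
        np.column_stack(cols), index=truth.index, columns=sample_ids
    )
    meta = pd.DataFrame(
        {"group": groups, "sex": sexes, "organ": "cardiac_fibroblast"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta), truth.reset_index()


# ---------------------------------------------------------------------------
# Organ counts
# ---------------------------------------------------------------------------


def organ_gene_universe(spec: OrganSpec) -> list[str]:
    width = len(str(spec.n_genes))
    return [f"gene{i + 1:0{width}d}" for i in range(spec.n_genes)]


def simulate_organ_counts(
    config: SimulationConfig,
) -> tuple[dict[str, CountMatrix], pd.DataFrame]:
    """Per-organ NB count matrices with planted aged-upregulated genes."""
    config.validate()
    spec = config.organ_spec
    if len(spec.organs) < 2:
        raise ValueError("need at least 2 organs")
    rng = _rng(config, 3)
    genes = organ_gene_universe(spec)
    n = spec.n_samples_per_group

    matrices: dict[str, CountMatrix] = {}
    truth_rows = []
    for organ in spec.organs:
        mu = spec.baseline_mean * np.exp(rng.normal(0.0, 1.0, size=len(genes)))
        fold = np.ones(len(genes))
        for gene, (organs, f) in spec.planted.items():
            if organ in organs:
                fold[genes.index(gene)] = f
                truth_rows.append({"organ": organ, "gene": gene, "fold": f})
        scale = spec.target_depth / mu.sum()
        cols, ids, grp = [], [], []
        for group, prefix in (("young", "y"), ("old", "o")):
            for j in range(n):
                mean_vec = mu * scale * rng.uniform(0.8, 1.2)
                if group == "old":
                    mean_vec = mean_vec * fold
                cols.append(_nb_draw(rng, mean_vec, spec.dispersion))
                ids.append(f"{organ}_{prefix}{j + 1}")
                grp.append(group)
        counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
        meta = pd.DataFrame(
            {"group": grp, "sex": "NA", "organ": organ},
            index=pd.Index(ids, name="sample_id"),
        )
        matrices[organ] = CountMatrix(counts=counts, sample_meta=meta)
    truth = pd.DataFrame(truth_rows, columns=["organ", "gene", "fold"])
    return matrices, truth


# ---------------------------------------------------------------------------
# Target databases and gene sets
# ---------------------------------------------------------------------------


def simulate_target_db(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Three prediction tables with a planted >=2-source consensus set.

    Planted pairs appear in 2 or 3 sources; decoys in exactly one.  The truth
    table lists the consensus (mirna, gene) pairs.
    """
    config.validate()
    spec = config.targetdb_spec
    if spec.n_universe < 50:
        raise ValueError("gene universe must have >= 50 symbols")
    rng = _rng(config, 4)
    width = len(str(config.organ_spec.n_genes))
    universe = [f"gene{i + 1:0{width}d}" for i in range(spec.n_universe)]
    mirnas = [f"mirg-{i + 1:0{len(str(config.n_mirna_genes))}d}-3p" for i in range(spec.n_mirnas)]

    tables: dict[str, list[dict]] = {s: [] for s in spec.sources}
    truth_rows = []
    # planted consensus pairs: gene i paired with a cluster miRNA, >=2 sources
    for i in range(spec.n_planted):
        gene = universe[i]
        mirna = mirnas[i % len(mirnas)]
        k = 2 if rng.random() < 0.5 else 3
        chosen = rng.choice(len(spec.sources), size=k, replace=False)
        for c in chosen:
            tables[spec.sources[c]].append(
                {"mirna": mirna, "gene": gene, "score": round(float(rng.uniform(0.7, 1.0)), 3)}
            )
        truth_rows.append({"mirna": mirna, "gene": gene, "n_sources": k})
    # decoys: single-source pairs on genes outside the planted block
    decoy_genes = universe[spec.n_planted:]
    for i in range(spec.n_decoys):
        gene = decoy_genes[i % len(decoy_genes)]
        mirna = mirnas[int(rng.integers(0, len(mirnas)))]
        src = spec.sources[int(rng.integers(0, len(spec.sources)))]
        if any(r["gene"] == gene and r["mirna"] == mirna for r in tables[src]):
            continue
        tables[src].append(
            {"mirna": mirna, "gene": gene, "score": round(float(rng.uniform(0.3, 1.0)), 3)}
        )
    out = {
        s: pd.DataFrame(rows, columns=["mirna", "gene", "score"]).sort_values(
            ["mirna", "gene"], ignore_index=True
        )
        for s, rows in tables.items()
    }
    truth = pd.DataFrame(truth_rows, columns=["mirna", "gene", "n_sources"])
    return out, truth


def simulate_gene_sets(config: SimulationConfig) -> tuple[dict[str, set[str]], str]:
    """Pathway gene sets over the target universe with one enriched term.

    The true term packs ``true_term_consensus`` planted consensus genes plus
    random filler; the remaining terms are uniform draws and stay unenriched.
    Returns (gene sets, name of the true term).
    """
    config.validate()
    spec = config.targetdb_spec
    rng = _rng(config, 5)
    width = len(str(config.organ_spec.n_genes))
    universe = np.array([f"gene{i + 1:0{width}d}" for i in range(spec.n_universe)])
    sets: dict[str, set[str]] = {}
    true_name = "PATH_TRUE"
    consensus_part = list(universe[: spec.true_term_consensus])
    filler = rng.choice(
        universe[spec.n_planted:], size=spec.term_size - spec.true_term_consensus,
        replace=False,
    )
    sets[true_name] = set(consensus_part) | set(filler.tolist())
    for t in range(spec.n_terms):
        members = rng.choice(universe, size=spec.term_size, replace=False)
        sets[f"PATH_{t + 1:02d}"] = set(members.tolist())
    return sets, true_name


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(config: SimulationConfig) -> pd.DataFrame:
    """Ct table under the comparative-CT measurement model.

    Target Ct = base + group delta-Ct shift + Gaussian noise; reference Ct is
    constant + noise.  A shift of +1 cycle therefore corresponds to a relative
    expression of 0.5 via 2^-ddCt.
    """
    config.validate()
    spec = config.qpcr_spec
    if len(spec.groups) < 2:
        raise ValueError("need >= 2 qPCR groups")
    if spec.n_per_group < 3:
        raise ValueError("need >= 3 samples per qPCR group")
    rng = _rng(config, 6)
    rows = []
    for group in spec.groups:
        shift = spec.shifts.get(group, 0.0)
        for j in range(spec.n_per_group):
            sid = f"{group}_{j + 1}"
            for assay in spec.assays:
                ct_t = spec.base_ct + shift + rng.normal(0.0, spec.noise_sd)
                ct_r = spec.reference_ct + rng.normal(0.0, spec.noise_sd)
                rows.append(
                    {
                        "sample_id": sid,
                        "group": group,
                        "organ_or_celltype": spec.context,
                        "target_assay": assay,
                        "ct_target": round(ct_t, 4),
                        "reference_assay": spec.reference_assay,
                        "ct_reference": round(ct_r, 4),
                    }
                )
    return pd.DataFrame(rows)
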
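"""End-to-end orchestration: simulate -> DE -> clusters -> targets ->
enrichment -> cross-organ integration -> qPCR, with machine-readable outputs.

Every stage writes its TSV/BED/JSON artifact into the output directory and
contributes to one summary JSON.  The whole run is a pure function of the
simulation config (seed included): re-running with the same config yields
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from . import clusters as cl
from . import enrichment as en
from . import expression as ex
from . import organs as og
from . import qpcr as qp
from . import synthetic as sy
from . import targets as tg
from .io import CountMatrix, write_bed, write_counts, write_ct_table, write_gmt, write_mirna_gff, write_target_table

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    sim: sy.SimulationConfig = dataclasses.field(default_factory=sy.SimulationConfig)
    de_params: ex.DEParams = dataclasses.field(default_factory=ex.DEParams)
    max_gap: int = cl.DEFAULT_MAX_GAP
    min_size: int = cl.DEFAULT_MIN_SIZE
    min_sources: int = 2
    enrich_params: en.EnrichParams = dataclasses.field(default_factory=en.EnrichParams)
    organ_params: og.OrganDEParams = dataclasses.field(default_factory=og.OrganDEParams)
    outdir: str = "megamir_out"


def _round(x: float, nd: int = 6) -> float:
    return float(np.round(float(x), nd))


def run_all(config: PipelineConfig) -> dict:
    """Execute the full synthetic pipeline and return the summary dict."""
    os.makedirs(config.outdir, exist_ok=True)
    out = config.outdir
    summary: dict = {"seed": int(config.sim.seed)}

    # -- simulate ------------------------------------------------------------
    logger.info("stage=simulate seed=%d", config.sim.seed)
    ann = sy.simulate_annotation(config.sim)
    write_mirna_gff(ann, os.path.join(out, "annotation.gff3"))
    counts, truth = sy.simulate_mirna_counts(ann, config.sim)
    write_counts(counts, os.path.join(out, "mirna_counts.tsv"),
                 os.path.join(out, "mirna_meta.tsv"))
    truth.to_csv(os.path.join(out, "mirna_truth.tsv"), sep="\t", index=False)
    organ_counts, organ_truth = sy.simulate_organ_counts(config.sim)
    for organ, cm in organ_counts.items():
        write_counts(cm, os.path.join(out, f"counts_{organ}.tsv"),
                     os.path.join(out, f"meta_{organ}.tsv"))
    organ_truth.to_csv(os.path.join(out, "organ_truth.tsv"), sep="\t", index=False)
    tables, target_truth = sy.simulate_target_db(config.sim)
    for source, df in tables.items():
        df.to_csv(os.path.join(out, f"targets_{source}.tsv"), sep="\t", index=False)
    target_truth.to_csv(os.path.join(out, "target_truth.tsv"), sep="\t", index=False)
    gene_sets, true_term = sy.simulate_gene_sets(config.sim)
    write_gmt(gene_sets, os.path.join(out, "pathways.gmt"))
    ct = sy.simulate_qpcr(config.sim)
    write_ct_table(ct, os.path.join(out, "qpcr_ct.tsv"))
    config.sim.to_yaml(os.path.join(out, "sim_config.yaml"))

    # -- differential expression --------------------------------------------
    logger.info("stage=de n_features=%d", len(counts.feature_ids))
    de = ex.run_de(counts, config.de_params)
    de.to_csv(os.path.join(out, "de.tsv"), sep="\t")
    class_counts = de["class"].value_counts().to_dict()
    summary["de"] = {
        "n_features": int(len(de)),
        "classes": {k: int(class_counts.get(k, 0))
                    for k in ("down", "steady", "up", "excluded")},
        "filter_theta": _round(de.attrs["filter_theta"], 2),
    }

    # -- genomic mapping and clusters ----------------------------------------
    positions, unmapped = cl.assign_positions(ann, list(de.index))
    freq = cl.chromosome_frequency(
        positions, de["class"].to_dict()
    )
    freq.to_csv(os.path.join(out, "chromosome_frequency.tsv"), sep="\t")
    arm_table = de.reset_index().rename(columns={"feature_id": "mature_id"})
    arm_table["gene_id"] = [
        ann.matures[m].parent_gene for m in arm_table["mature_id"]
    ]
    arm_table["arm"] = [ann.matures[m].arm for m in arm_table["mature_id"]]
    strand_sel = cl.dominant_strand(arm_table)
    strand_sel.to_csv(os.path.join(out, "dominant_strand.tsv"), sep="\t")
    gene_pos = {g.gene_id: (g.chrom, g.start) for g in ann.genes.values()}
    found = cl.detect_clusters(gene_pos, config.max_gap, config.min_size)
    gene_fc = strand_sel["log2fc"].to_dict()
    for c in found:
        cl.locus_coordination(c, gene_fc)
        comp = strand_sel.loc[
            [g for g in c.member_genes if g in strand_sel.index], "gene_class"
        ].value_counts().to_dict()
        c.composition = {k: int(comp.get(k, 0))
                         for k in ("down", "steady", "up", "excluded")}
        c.n_mature = int(
            arm_table["gene_id"].isin(c.member_genes).sum()
        )
    write_bed(found, os.path.join(out, "clusters.bed"))
    cluster_records = [
        {
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "start": int(c.start),
            "end": int(c.end),
            "span_bp": int(c.span_bp),
            "n_genes": len(c.member_genes),
            "n_mature": c.n_mature,
            "composition": c.composition,
            "n_negative_fc": c.n_negative_fc,
            "n_members_tested": c.n_members_tested,
            "binomial_p": None if c.binomial_p is None else float(f"{c.binomial_p:.3e}"),
        }
        for c in found
    ]
    with open(os.path.join(out, "clusters.json"), "w") as fh:
        json.dump(cluster_records, fh, indent=1, sort_keys=True)
    summary["clusters"] = cluster_records
    summary["n_unmapped"] = len(unmapped)

    # -- consensus targets and enrichment ------------------------------------
    pred = [
        pd.DataFrame(
            {"source": source, "mirna_id": df["mirna"],
             "gene_symbol": df["gene"], "score": df["score"]}
        )
        for source, df in tables.items()
    ]
    consensus = tg.consensus_targets(pred, config.min_sources)
    consensus.pairs.to_csv(os.path.join(out, "consensus.tsv"), sep="\t", index=False)
    universe = set().union(*gene_sets.values())
    query = consensus.all_genes() & universe
    enrich = en.hypergeometric_enrichment(
        query, gene_sets, universe, config.enrich_params
    )
    grouped = en.kappa_group_terms(
        enrich, universe, config.enrich_params.kappa_threshold
    )
    enrich_out = enrich.drop(columns=["hits"]).join(
        grouped[["group_id", "is_group_leader"]]
    )
    enrich_out.to_csv(os.path.join(out, "enrichment.tsv"), sep="\t")
    candidates = en.reported_genes(enrich)
    summary["targets"] = {
        "n_consensus_pairs": int(len(consensus.pairs)),
        "n_consensus_genes": int(len(consensus.all_genes())),
        "n_terms_reported": int(enrich["reported"].sum()),
        "n_candidate_genes": int(len(candidates)),
        "true_term_reported": bool(
            true_term in enrich.index and enrich.loc[true_term, "reported"]
        ),
    }

    # -- organ DE and intersection --------------------------------------------
    organ_up: dict[str, set[str]] = {}
    for organ, cm in organ_counts.items():
        up, down, _res = og.organ_de(cm, config.organ_params)
        organ_up[organ] = up
    hits = og.cross_organ_intersect(organ_up, candidates)
    hits_df = pd.DataFrame(
        [
            {"gene": h.gene, "n_organs_up": h.n_organs_up,
             "organs_up": ",".join(h.organs_up)}
            for h in hits
        ],
        columns=["gene", "n_organs_up", "organs_up"],
    )
    hits_df.to_csv(os.path.join(out, "cross_organ_hits.tsv"), sep="\t", index=False)
    summary["cross_organ"] = {
        "n_hits": len(hits),
        "hits": [
            {"gene": h.gene, "n_organs_up": h.n_organs_up, "organs_up": h.organs_up}
            for h in hits
        ],
    }

    # -- qPCR ------------------------------------------------------------------
    rq = qp.comparative_ct(ct, reference_group="young")
    rq.to_csv(os.path.join(out, "qpcr_rq.tsv"), sep="\t", index=False)
    comps = qp.compare_groups_per_assay(rq)
    comps.to_csv(os.path.join(out, "qpcr_stats.tsv"), sep="\t", index=False)
    gsum = qp.group_summary(rq)
    summary["qpcr"] = {
        "n_assays": int(rq["target_assay"].nunique()),
        "mean_rq_by_group": {
            g: _round(v, 4)
            for g, v in gsum.groupby("group")["mean_rq"].mean().items()
        },
        "tests": [
            {"assay": r["target_assay"], "test": r["test_used"],
             "p": _round(r["pvalue"], 6)}
            for r in comps.to_dict("records")
        ],
    }

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def make_report(outdir: str) -> str:
    """Render the human-readable report from the stage outputs on disk."""
    path = os.path.join(outdir, "summary.json")
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing stage output {path}")
    with open(path) as fh:
        summary = json.load(fh)
    lines = ["# megamir pipeline report", ""]
    de = summary["de"]
    lines += [
        "## miRNA differential expression",
        f"features analyzed: {de['n_features']}",
        "class counts: "
        + ", ".join(f"{k}={v}" for k, v in sorted(de["classes"].items())),
        f"independent-filter quantile: {de['filter_theta']}",
        "",
        "## chromosome frequencies",
    ]
    freq = pd.read_csv(os.path.join(outdir, "chromosome_frequency.tsv"), sep="\t", index_col=0)
    lines.append(freq.to_string())
    lines += ["", "## clusters"]
    for c in summary["clusters"]:
        lines.append(
            f"{c['cluster_id']}: {c['chrom']}:{c['start']}-{c['end']} "
            f"({c['span_bp']} bp, {c['n_genes']} genes; "
            f"composition {c['composition']}; sign-test p={c['binomial_p']})"
        )
    t = summary["targets"]
    lines += [
        "",
        "## targets & enrichment",
        f"consensus pairs: {t['n_consensus_pairs']} "
        f"({t['n_consensus_genes']} genes); "
        f"reported terms: {t['n_terms_reported']}; "
        f"candidate genes: {t['n_candidate_genes']}",
        "",
        "## cross-organ hits",
    ]
    for h in summary["cross_organ"]["hits"]:
        lines.append(f"{h['gene']}: up in {h['n_organs_up']} organs "
                     f"({', '.join(h['organs_up'])})")
    if not summary["cross_organ"]["hits"]:
        lines.append("(none)")
    lines += ["", "## qPCR group means (relative expression)"]
    for g, v in sorted(summary["qpcr"]["mean_rq_by_group"].items()):
        lines.append(f"{g}: {v}")
    report = "\n".join(lines) + "\n"
    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        fh.write(report)
    return report
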
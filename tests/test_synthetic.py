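import dataclasses

import numpy as np
import pandas as pd
import pytest

from megamir import io as mio
from megamir import synthetic as sy


def small_config(**kw) -> sy.SimulationConfig:
    base = dict(
        seed=11,
        n_chromosomes=2,
        n_mirna_genes=30,
        cluster_spec=sy.ClusterSpec(n_genes=20),
    )
    base.update(kw)
    return sy.SimulationConfig(**base)


class TestAnnotation:
    def test_minimal_single_gene(self):
        cfg = sy.SimulationConfig(
            seed=0, n_chromosomes=1, n_mirna_genes=1,
            cluster_spec=sy.ClusterSpec(n_genes=1),
        )
        ann = sy.simulate_annotation(cfg)
        assert len(ann.genes) == 1 and len(ann.matures) == 2

    def test_cluster_span_arithmetic(self, default_config, annotation):
        cs = default_config.cluster_spec
        cluster = [g for g in annotation.genes.values() if g.locus_label == "megacluster"]
        assert len(cluster) == cs.n_genes
        assert {g.chrom for g in cluster} == {cs.chrom}
        starts = sorted(g.start for g in cluster)
        ends = sorted(g.end for g in cluster)
        # bounding span = n gene lengths + (n-1) inter-gene gaps
        expected = cs.n_genes * sy.GENE_LEN + (cs.n_genes - 1) * cs.gap
        assert ends[-1] - starts[0] + 1 == expected
        # consecutive spacing is exactly gene length + gap
        assert set(np.diff(starts)) == {sy.GENE_LEN + cs.gap}

    def test_background_genes_exceed_max_gap(self, annotation):
        from megamir.clusters import DEFAULT_MAX_GAP

        by_chrom = {}
        for g in annotation.genes.values():
            if g.locus_label is None:
                by_chrom.setdefault(g.chrom, []).append(g.start)
        for starts in by_chrom.values():
            if len(starts) > 1:
                assert min(np.diff(sorted(starts))) > DEFAULT_MAX_GAP

    def test_same_seed_byte_identical_gff(self, tmp_path, default_config):
        a, b = tmp_path / "a.gff3", tmp_path / "b.gff3"
        mio.write_mirna_gff(sy.simulate_annotation(default_config), str(a))
        mio.write_mirna_gff(sy.simulate_annotation(default_config), str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_cluster_span_overflow_rejected(self):
        with pytest.raises(ValueError, match="span"):
            sy.simulate_annotation(
                small_config(cluster_spec=sy.ClusterSpec(start=10**6, n_genes=20),
                             chrom_length=10**6)
            )


class TestMirnaCounts:
    def test_null_effect_empty_truth(self, default_config):
        cfg = dataclasses.replace(default_config, locus_effect=1.0)
        ann = sy.simulate_annotation(cfg)
        _, truth = sy.simulate_mirna_counts(ann, cfg)
        assert not truth["affected"].any()

    def test_truth_marks_only_planted(self, mirna_bundle, default_config):
        _, truth = mirna_bundle
        n_cluster = default_config.cluster_spec.n_genes
        expected_genes = round(default_config.frac_cluster_affected * n_cluster)
        assert truth[truth["affected"]]["gene_id"].nunique() == expected_genes
        assert (truth.loc[truth["affected"], "is_cluster"]).all()
        assert (truth.loc[~truth["affected"], "true_ratio"] == 1.0).all()

    def test_determinism(self, default_config, annotation):
        a, _ = sy.simulate_mirna_counts(annotation, default_config)
        b, _ = sy.simulate_mirna_counts(annotation, default_config)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_empirical_repression_ratio(self):
        # Monte-Carlo mean over the truth set: ~1e4 arms, minority affected so
        # per-sample depth can be estimated from the unaffected majority.
        cfg = sy.SimulationConfig(
            seed=4, n_chromosomes=3, n_mirna_genes=5000,
            cluster_spec=sy.ClusterSpec(n_genes=500), frac_cluster_affected=1.0,
            locus_effect=0.6,
        )
        ann = sy.simulate_annotation(cfg)
        cm, truth = sy.simulate_mirna_counts(ann, cfg)
        truth = truth.set_index("feature_id")
        aff = truth["affected"].to_numpy()
        y = cm.counts.to_numpy(dtype=float)
        depth = y[~aff].sum(axis=0)  # unaffected arms as the depth reference
        norm = y / depth * depth.mean()
        old = np.asarray(cm.groups()) == "old"
        ratio = norm[np.ix_(aff, old)].sum() / norm[np.ix_(aff, ~old)].sum()
        assert ratio == pytest.approx(0.6, abs=0.02)

    def test_arm_ratio_of_grand_means(self, default_config, annotation, mirna_bundle):
        cm, truth = mirna_bundle
        y = cm.counts.to_numpy(dtype=float)
        # dominant arm = larger base_mean within each gene
        t = truth.reset_index()
        dom_mask = t.groupby("gene_id")["base_mean"].transform("max") == t["base_mean"]
        grand_dom = y[dom_mask.to_numpy()].mean()
        grand_min = y[~dom_mask.to_numpy()].mean()
        assert grand_dom / grand_min == pytest.approx(
            default_config.arm_ratio, rel=0.10
        )

    def test_overdispersion_sanity(self):
        # phi > 0 -> variance/mean above 1; phi = 0 -> Poisson-like
        def depth_normalized_vmr(cm):
            y = cm.counts.to_numpy(dtype=float)[:, :6]  # one group only
            # leave-one-out library totals: a feature must not normalize away
            # its own fluctuations
            loo = y.sum(axis=0)[None, :] - y
            y = y / loo * loo.mean(axis=1)[:, None]
            hi = y.mean(axis=1) > 50
            return y[hi].var(axis=1, ddof=1) / y[hi].mean(axis=1)

        # with 6 samples the per-feature VMR is chi2_5/5-distributed around
        # its truth (median ~0.87), so bounds are generous
        rng_cfg = small_config(n_mirna_genes=150, cluster_spec=sy.ClusterSpec(n_genes=20),
                               dispersion=0.2, seed=5)
        cm, _ = sy.simulate_mirna_counts(sy.simulate_annotation(rng_cfg), rng_cfg)
        assert np.median(depth_normalized_vmr(cm)) > 2.0
        poi_cfg = small_config(n_mirna_genes=150, cluster_spec=sy.ClusterSpec(n_genes=20),
                               dispersion=0.0, seed=5)
        cm2, _ = sy.simulate_mirna_counts(sy.simulate_annotation(poi_cfg), poi_cfg)
        assert 0.6 <= np.median(depth_normalized_vmr(cm2)) <= 1.35

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            small_config(dispersion=-0.1).validate()
        with pytest.raises(ValueError):
            small_config(baseline_mean=0.0).validate()


class TestOrganCounts:
    def test_truth_bookkeeping(self, default_config):
        _, truth = sy.simulate_organ_counts(default_config)
        g1 = truth[truth["gene"] == "gene0001"]
        assert len(g1) == 4 and set(g1["organ"]) == {"organ1", "organ2", "organ3", "organ4"}

    def test_null_organ_has_empty_truth(self, default_config):
        spec = dataclasses.replace(
            default_config.organ_spec,
            planted={"gene0001": (("organ1", "organ2", "organ3", "organ4"), 2.0)},
        )
        cfg = dataclasses.replace(default_config, organ_spec=spec)
        _, truth = sy.simulate_organ_counts(cfg)
        for organ in ("organ5", "organ6"):
            assert truth[truth["organ"] == organ].empty

    def test_up_fold_must_exceed_one(self, default_config):
        cfg = dataclasses.replace(
            default_config,
            organ_spec=dataclasses.replace(
                default_config.organ_spec, planted={"gene0001": (("organ1",), 0.8)}
            ),
        )
        with pytest.raises(ValueError, match="fold"):
            sy.simulate_organ_counts(cfg)


class TestTargetDb:
    def test_planted_in_two_plus_sources_decoys_in_one(self, default_config):
        tables, truth = sy.simulate_target_db(default_config)
        support = {}
        for source, df in tables.items():
            for _, r in df.iterrows():
                support.setdefault((r["mirna"], r["gene"]), set()).add(source)
        planted = set(zip(truth["mirna"], truth["gene"]))
        for pair, sources in support.items():
            if pair in planted:
                assert len(sources) >= 2
            else:
                assert len(sources) == 1

    def test_no_planted_pairs_empty_truth(self, default_config):
        cfg = dataclasses.replace(
            default_config,
            targetdb_spec=dataclasses.replace(default_config.targetdb_spec, n_planted=0),
        )
        _, truth = sy.simulate_target_db(cfg)
        assert truth.empty

    def test_determinism(self, default_config):
        ta, _ = sy.simulate_target_db(default_config)
        tb, _ = sy.simulate_target_db(default_config)
        for s in ta:
            pd.testing.assert_frame_equal(ta[s], tb[s])


class TestQpcr:
    def test_noiseless_exact_shifts(self, default_config):
        spec = dataclasses.replace(
            default_config.qpcr_spec, noise_sd=0.0,
            shifts={"young": 0.0, "old": 1.0, "very_old": 2.0},
        )
        cfg = dataclasses.replace(default_config, qpcr_spec=spec)
        ct = sy.simulate_qpcr(cfg)
        from megamir.qpcr import comparative_ct

        rq = comparative_ct(ct, "young")
        for group, expected in (("young", 1.0), ("old", 0.5), ("very_old", 0.25)):
            got = rq.loc[rq["group"] == group, "rq"]
            assert np.allclose(got, expected)

    def test_null_shifts_center_on_one(self, default_config):
        spec = dataclasses.replace(
            default_config.qpcr_spec, shifts={}, n_per_group=30
        )
        cfg = dataclasses.replace(default_config, qpcr_spec=spec)
        ct = sy.simulate_qpcr(cfg)
        from megamir.qpcr import comparative_ct

        rq = comparative_ct(ct, "young")
        means = rq.groupby("group")["rq"].mean()
        assert np.allclose(means, 1.0, atol=0.25)

    def test_negative_noise_rejected(self, default_config):
        spec = dataclasses.replace(default_config.qpcr_spec, noise_sd=-1.0)
        cfg = dataclasses.replace(default_config, qpcr_spec=spec)
        with pytest.raises(ValueError, match="noise"):
            sy.simulate_qpcr(cfg)


class TestConfigYaml:
    def test_yaml_round_trip(self, tmp_path, default_config):
        path = tmp_path / "sim.yaml"
        default_config.to_yaml(str(path))
        back = sy.SimulationConfig.from_yaml(str(path))
        assert back == default_config
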
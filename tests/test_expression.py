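import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from megamir import expression as ex
from megamir import synthetic as sy
from tests.conftest import build_count_matrix, nb_draws

GRP6 = ["young"] * 6 + ["old"] * 6
ONES12 = np.ones(12)


def bh_bruteforce(p):
    """Literal step-up definition: adj_i = min over j>=rank(i) of m p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        candidates = [m * p[order[j - 1]] / j for j in range(rank, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


class TestRpm:
    def test_single_feature_forces_million(self):
        cm = build_count_matrix(np.array([[100, 7]]), ["young", "old"])
        rpm = ex.rpm_normalize(cm)
        assert np.allclose(rpm.to_numpy(), 1e6)

    def test_arithmetic_identity(self):
        cm = build_count_matrix(np.array([[25], [75]]), ["young"])
        assert np.allclose(ex.rpm_normalize(cm).to_numpy().ravel(), [250000.0, 750000.0])

    def test_columns_sum_to_million(self, mirna_bundle):
        cm, _ = mirna_bundle
        sums = ex.rpm_normalize(cm).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 100, size=(30, 4))
        a = ex.rpm_normalize(build_count_matrix(y, ["young"] * 4))
        b = ex.rpm_normalize(build_count_matrix(y * 7, ["young"] * 4))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_sample_rejected(self):
        cm = build_count_matrix(np.array([[0, 5]]), ["young", "old"])
        with pytest.raises(ValueError, match="zero total"):
            ex.rpm_normalize(cm)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
            ([0.01, 0.02, 0.03, 0.5], [0.04, 0.04, 0.04, 0.5]),
        ],
    )
    def test_hand_cases(self, p, expected):
        assert np.allclose(ex.benjamini_hochberg(np.array(p)), expected)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_bruteforce_stepup(self, p):
        assert np.allclose(ex.benjamini_hochberg(np.array(p)), bh_bruteforce(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ex.benjamini_hochberg(np.array([0.5, 1.5]))


class TestDispersion:
    def test_poisson_truth_recovered_as_zero(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(200, size=(2000, 12))
        phi = ex.estimate_dispersion(build_count_matrix(y, GRP6), shrink=0.0)
        assert np.median(phi) <= 0.01

    def test_nb_truth_recovered(self):
        rng = np.random.default_rng(2)
        y = nb_draws(rng, 500, 0.1, (2000, 12))
        phi = ex.estimate_dispersion(build_count_matrix(y, GRP6), shrink=0.0)
        assert 0.05 <= np.median(phi) <= 0.2

    def test_constant_counts_floored_at_zero(self):
        y = np.full((5, 12), 50)
        phi = ex.estimate_dispersion(build_count_matrix(y, GRP6), shrink=0.0)
        assert np.allclose(phi, 0.0)

    def test_single_sample_group_rejected(self):
        y = np.ones((3, 3), dtype=int)
        cm = build_count_matrix(y, ["young", "young", "old"])
        with pytest.raises(ValueError, match="fewer than 2"):
            ex.estimate_dispersion(cm)


class TestNbGroupTest:
    def test_null_pvalues_uniform_known_phi(self):
        rng = np.random.default_rng(3)
        y = nb_draws(rng, 500, 0.1, (2000, 12))
        cm = build_count_matrix(y, GRP6)
        res = ex.nb_group_test(cm, phi=np.full(2000, 0.1), offsets=ONES12)
        assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_power_on_planted_repression(self):
        # mu=500, phi=0.05, ratio 0.6, n=6/group: discovery at BH 0.05
        rng = np.random.default_rng(4)
        y = np.hstack(
            [nb_draws(rng, 500, 0.05, (500, 6)), nb_draws(rng, 300, 0.05, (500, 6))]
        )
        cm = build_count_matrix(y, GRP6)
        phi = ex.estimate_dispersion(cm)
        ddf = ex.moderated_denominator_df(12, 0.9)
        res = ex.nb_group_test(cm, phi=phi, offsets=ONES12, denom_df=ddf)
        fdr = ex.benjamini_hochberg(res["pvalue"].to_numpy())
        power = ((fdr < 0.05) & (res["log2fc"].to_numpy() < 0)).mean()
        assert power >= 0.8

    def test_all_zero_feature_convention(self):
        y = np.vstack([np.zeros(12, dtype=int), np.full(12, 100)])
        cm = build_count_matrix(y, GRP6)
        res = ex.nb_group_test(cm, phi=np.array([0.1, 0.1]))
        assert res.iloc[0]["pvalue"] == 1.0 and res.iloc[0]["log2fc"] == 0.0

    def test_fdr_control_over_null_replicates(self):
        # realized false-discovery proportion at BH 0.05 across null runs
        rng = np.random.default_rng(5)
        fdps = []
        ddf = ex.moderated_denominator_df(12, 0.9)
        for _ in range(100):
            y = nb_draws(rng, 500, 0.1, (600, 12))
            cm = build_count_matrix(y, GRP6)
            phi = ex.estimate_dispersion(cm)
            res = ex.nb_group_test(cm, phi=phi, denom_df=ddf)
            rejected = ex.benjamini_hochberg(res["pvalue"].to_numpy()) < 0.05
            fdps.append(1.0 if rejected.any() else 0.0)
        assert np.mean(fdps) <= 0.08


class TestIndependentFilter:
    def test_all_high_signal_keeps_everything(self):
        params = ex.DEParams()
        mean_rpm = np.linspace(100, 1000, 50)
        p = np.full(50, 1e-6)
        kept, theta, fdr = ex.independent_filter(mean_rpm, p, params)
        assert theta == 0.0 and kept.all()

    def test_single_feature(self):
        kept, theta, fdr = ex.independent_filter(
            np.array([10.0]), np.array([0.5]), ex.DEParams()
        )
        assert theta == 0.0 and kept.all()

    def test_filtering_rescues_marginal_signals(self):
        # half low-abundance pure noise, half abundant marginal signals:
        # dropping the noise halves the BH denominator and rescues the block
        rng = np.random.default_rng(6)
        n = 500
        mean_rpm = np.concatenate([rng.uniform(0, 10, n), rng.uniform(100, 1000, n)])
        p = np.concatenate([rng.uniform(0, 1, n), 0.001 + 0.049 * rng.random(n)])
        params = ex.DEParams()
        kept, theta, fdr = ex.independent_filter(mean_rpm, p, params)
        assert theta >= 0.4
        rej_theta = (fdr[kept] < params.alpha).sum()
        rej_zero = (ex.benjamini_hochberg(p) < params.alpha).sum()
        assert rej_theta >= rej_zero
        # argmax agrees with an exhaustive scan of the same grid
        best = max(
            (int((ex.benjamini_hochberg(
                p[mean_rpm >= np.quantile(mean_rpm, t)]) < params.alpha).sum()), -t)
            for t in params.filter_quantiles
        )
        assert rej_theta == best[0] and theta == -best[1]

    def test_excluded_features_get_nan_fdr(self):
        rng = np.random.default_rng(7)
        mean_rpm = np.concatenate([np.zeros(50), np.full(50, 1000.0)])
        p = np.concatenate([rng.uniform(0, 1, 50), np.full(50, 1e-8)])
        kept, theta, fdr = ex.independent_filter(mean_rpm, p, ex.DEParams())
        assert np.isnan(fdr[~kept]).all() and not np.isnan(fdr[kept]).any()


class TestClassification:
    def make_de(self, fdr, log2fc):
        return pd.DataFrame({"fdr": [fdr], "log2fc": [log2fc]}, index=["f"])

    def test_down_call(self):
        cls = ex.classify_features(self.make_de(0.01, -0.5), ex.DEParams())
        assert cls.iloc[0] == "down"

    def test_steady_when_not_significant(self):
        cls = ex.classify_features(self.make_de(0.2, -3.0), ex.DEParams())
        assert cls.iloc[0] == "steady"

    def test_min_change_floor_demotes_small_shifts(self):
        # 2^-0.2 - 1 = -13%: below a 25% floor despite FDR significance
        cls = ex.classify_features(
            self.make_de(0.01, -0.2), ex.DEParams(min_change=0.25)
        )
        assert cls.iloc[0] == "steady"

    def test_partition_is_exhaustive(self, mirna_bundle):
        cm, _ = mirna_bundle
        de = ex.run_de(cm)
        assert de["class"].isin(["down", "steady", "up", "excluded"]).all()
        assert ((de["class"] == "excluded") == de["fdr"].isna()).all()


class TestDistributionSummary:
    def test_constant_vector(self):
        s = ex.distribution_summary(np.full(10, 5.0))
        assert s.iqr == 0 and s.upper_fence == 5.0 and s.outlier_fraction == 0.0

    def test_interpolated_quartiles_one_to_eight(self):
        s = ex.distribution_summary(np.arange(1.0, 9.0))
        assert (s.q1, s.q3, s.upper_fence) == (2.75, 6.25, 11.5)

    def test_outlier_fraction_matches_direct_count(self):
        rng = np.random.default_rng(8)
        v = np.exp(rng.normal(3, 1.5, size=500))
        s = ex.distribution_summary(v)
        q1, q3 = np.percentile(v, [25, 75])
        assert s.outlier_fraction == (v > q3 + 1.5 * (q3 - q1)).mean()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ex.distribution_summary(np.array([1.0, 2.0, 3.0]))


class TestSexStratification:
    @staticmethod
    def _make(rng, male_only_idx, both_idx, n_feat=60):
        sexes = (["M"] * 3 + ["F"] * 3) * 2
        mu = np.full((n_feat, 12), 2000.0)
        for j, sex in enumerate(sexes):
            old = j >= 6
            if old and sex == "M":
                mu[male_only_idx, j] *= 0.1
            if old:
                mu[both_idx, j] *= 0.1
        y = nb_draws(rng, mu, 0.05, mu.shape)
        return build_count_matrix(y, GRP6, sexes=sexes)

    def test_male_only_effects_flagged_shared_effects_not(self):
        rng = np.random.default_rng(9)
        male_only, both = np.arange(5), np.arange(5, 10)
        cm = self._make(rng, male_only, both)
        flags = ex.sex_stratified_flags(cm)
        assert flags.iloc[male_only].mean() >= 0.8
        assert flags.iloc[both].mean() <= 0.2

    def test_no_effects_flag_rate_within_alpha(self):
        # all-null matrix: per-sex BH at 0.05 leaves flags at the error rate
        rng = np.random.default_rng(11)
        sexes = (["M"] * 3 + ["F"] * 3) * 2
        y = nb_draws(rng, 500, 0.05, (200, 12))
        cm = build_count_matrix(y, GRP6, sexes=sexes)
        flags = ex.sex_stratified_flags(cm)
        assert flags.mean() <= 0.05

    def test_missing_sex_yields_na(self):
        rng = np.random.default_rng(10)
        y = nb_draws(rng, 100, 0.05, (10, 12))
        cm = build_count_matrix(y, GRP6, sexes=["M"] * 12)
        flags = ex.sex_stratified_flags(cm)
        assert flags.isna().all()


class TestParameterRecovery:
    def test_planted_repression_recovered_on_default_bundle(
        self, default_config, mirna_bundle
    ):
        cm, truth = mirna_bundle
        de = ex.run_de(cm)
        true_rpm = truth["base_mean"] / truth["base_mean"].sum() * 1e6
        aff = truth["affected"].to_numpy()
        hi = (true_rpm > 100).to_numpy()
        down = (de["class"].to_numpy() == "down")
        assert down[aff & hi].mean() >= 0.70
        false_calls = np.isin(de["class"].to_numpy()[~aff], ["down", "up"])
        assert false_calls.mean() < 0.10
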
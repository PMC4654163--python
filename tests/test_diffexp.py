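import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from flaresig.diffexp import (DesignSpec, ExpressionLinearModel, GeneFits,
                              ModeratedFits, call_significant, enfp_alpha,
                              estimate_prior, fit_linear_models,
                              moderated_test, posterior_variances,
                              rtpcr_concordance, smooth_variances,
                              venn_partition)
from flaresig.io import ValidationError
from flaresig.normalization import normalize_pipeline
from flaresig.simulate import SimConfig, simulate_study

from conftest import make_expr, make_meta


def design_frame(cols, assays):
    return pd.DataFrame(cols, index=assays)


class TestLinearFits:
    def test_intercept_only_recovers_mean_and_variance(self):
        expr = make_expr([[1.0, 2.0, 3.0]])
        design = design_frame({"Intercept": [1.0, 1.0, 1.0]}, expr.assay_ids)
        fits = fit_linear_models(expr, design)
        assert fits.coef.iloc[0, 0] == pytest.approx(2.0)
        assert fits.s2.iloc[0] == pytest.approx(1.0)
        assert fits.df_resid == 2

    def test_two_group_hand_ols(self):
        expr = make_expr([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]])
        design = design_frame({"Intercept": [1.0] * 6,
                               "group_CR": [0, 0, 0, 1, 1, 1]},
                              expr.assay_ids)
        fits = fit_linear_models(expr, design)
        assert fits.coef.loc["g0", "group_CR"] == pytest.approx(1.0)
        assert fits.s2.iloc[0] == pytest.approx(1.0)
        assert fits.df_resid == 4

    def test_group_confounded_with_batch_lists_columns(self):
        meta = make_meta([("a1", "s1", "control", "B1"),
                          ("a2", "s2", "control", "B1"),
                          ("a3", "s3", "CR", "B2"),
                          ("a4", "s4", "CR", "B2")])
        with pytest.raises(ValidationError, match="rank deficient"):
            DesignSpec(include_batch=True).build(meta)


def brute_force_prior(s2, df):
    """Independent solve of the log-variance moment equations.

    Matches mean/variance of log s^2 to the scaled-F law by bracketed
    root-finding, without the package's Newton trigamma inversion.
    """
    z = np.log(np.asarray(s2, dtype=float))
    zbar, zvar = z.mean(), z.var(ddof=1)
    gap = zvar - special.polygamma(1, df / 2.0)
    if gap <= 0:
        return np.inf, float(np.exp(zbar - special.digamma(df / 2.0)
                                    + np.log(df / 2.0)))

    def f(d0):
        return special.polygamma(1, d0 / 2.0) - gap

    d0 = optimize.brentq(f, 1e-6, 1e9, xtol=1e-12, rtol=1e-14)
    log_s0 = (zbar - special.digamma(df / 2.0) + np.log(df / 2.0)
              + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(np.exp(log_s0))


class TestVarianceSmoothing:
    def test_equal_variances_collapse_to_common_value(self):
        fits = GeneFits(
            coef=pd.DataFrame(np.zeros((12, 1)), columns=["Intercept"]),
            s2=pd.Series(np.full(12, 3.0)), df_resid=5,
            xtx_inv=np.eye(1), design_columns=["Intercept"])
        mfits = smooth_variances(fits)
        assert np.isinf(mfits.d0)
        assert mfits.s0_sq == pytest.approx(3.0, rel=1e-12)
        np.testing.assert_allclose(mfits.post_var.to_numpy(), 3.0)

    def test_recovery_of_simulated_hyperparameters(self):
        # s^2 ~ s0^2 * F(d, d0) with d0=4, s0^2=2, d=6
        rng = np.random.default_rng(8)
        d0, s0_sq, d = 4.0, 2.0, 6
        s2 = s0_sq * (rng.chisquare(d, 5000) / d) / (rng.chisquare(d0, 5000) / d0)
        d0_hat, s0_hat = estimate_prior(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.25
        assert abs(s0_hat - s0_sq) / s0_sq < 0.10

    def test_matches_brute_force_moment_solution(self):
        # fixed printed ensemble of 20 variances
        s2 = np.array([0.61, 1.93, 0.42, 2.88, 1.10, 0.75, 3.41, 0.28,
                       1.52, 0.96, 2.10, 0.55, 1.25, 4.02, 0.81, 1.71,
                       0.33, 2.45, 1.05, 0.68])
        df = 6
        d0_ref, s0_ref = brute_force_prior(s2, df)
        d0_hat, s0_hat = estimate_prior(s2, df)
        assert d0_hat == pytest.approx(d0_ref, abs=1e-8)
        assert s0_hat == pytest.approx(s0_ref, abs=1e-8)
        post_ref = (d0_ref * s0_ref + df * s2) / (d0_ref + df)
        np.testing.assert_allclose(
            posterior_variances(s2, df, d0_hat, s0_hat), post_ref, atol=1e-8)

    def test_posterior_between_sample_and_prior(self):
        rng = np.random.default_rng(9)
        s2 = rng.chisquare(5, 200) / 5
        d0_hat, s0_hat = estimate_prior(s2, 5)
        post = posterior_variances(s2, 5, d0_hat, s0_hat)
        lo = np.minimum(s2, s0_hat)
        hi = np.maximum(s2, s0_hat)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_all_zero_variances_rejected(self):
        fits = GeneFits(
            coef=pd.DataFrame(np.zeros((12, 1)), columns=["Intercept"]),
            s2=pd.Series(np.zeros(12)), df_resid=5,
            xtx_inv=np.eye(1), design_columns=["Intercept"])
        with pytest.raises(ValidationError, match="zero"):
            smooth_variances(fits)


def toy_mfits(values_a, values_b, d0=0.0, s0_sq=None):
    """Two-group fits from raw values, with a chosen prior."""
    vals = np.concatenate([values_a, values_b])
    expr = make_expr(vals[None, :])
    design = design_frame(
        {"Intercept": [1.0] * len(vals),
         "group_CR": [0.0] * len(values_a) + [1.0] * len(values_b)},
        expr.assay_ids)
    fits = fit_linear_models(expr, design)
    if s0_sq is None:
        s0_sq = float(fits.s2.iloc[0]) or 1.0
    post = posterior_variances(fits.s2.to_numpy(), fits.df_resid, d0, s0_sq)
    return ModeratedFits(fits=fits, d0=d0, s0_sq=s0_sq,
                         post_var=pd.Series(post, index=fits.s2.index))


class TestModeratedTest:
    def test_identical_group_means_give_t0_p1(self):
        mfits = toy_mfits([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        tab = moderated_test(mfits, np.array([0.0, 1.0]))
        assert tab["t"].iloc[0] == pytest.approx(0.0)
        assert tab["p"].iloc[0] == pytest.approx(1.0)

    def test_d0_zero_equals_classical_pooled_t(self):
        a = [1.2, 2.4, 1.9, 3.0]
        b = [2.8, 3.5, 4.1]
        mfits = toy_mfits(a, b, d0=0.0)
        tab = moderated_test(mfits, np.array([0.0, 1.0]))
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert tab["t"].iloc[0] == pytest.approx(ref.statistic)
        assert tab["p"].iloc[0] == pytest.approx(ref.pvalue)

    def test_infinite_prior_df_gives_normal_limit(self):
        a = [1.0, 2.0, 3.0, 2.5]
        b = [4.0, 5.0, 4.5]
        mfits = toy_mfits(a, b, d0=np.inf, s0_sq=1.3)
        tab = moderated_test(mfits, np.array([0.0, 1.0]))
        # statistic is a z with variance s0^2; df capped at 1e6
        diff = np.mean(b) - np.mean(a)
        se = np.sqrt(1.3 * (1 / 4 + 1 / 3))
        assert tab["t"].iloc[0] == pytest.approx(diff / se)
        assert tab["p"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(abs(diff / se)), rel=1e-4)

    def test_planted_log2fc_recovered_within_tolerance(self):
        # 2-log2 (four-fold) effects at study-matched sizes n=5 vs 4 and a
        # study-like planted fraction (~5% of expressed genes)
        planted = {"CR": [(i, 2.0) for i in range(20)]}
        cfg = SimConfig(group_sizes={"control": 4, "CR": 5},
                        batch_sizes=(5,), de_spec=planted, seed=13)
        study = simulate_study(cfg)
        expr = normalize_pipeline(study.counts)
        res = ExpressionLinearModel(expr, study.meta,
                                    include_batch=False).fit()
        tab = res.contrast("CR-control").set_index("gene")
        genes = [g for g, _ in study.truth.true_de["CR"]]
        err = (tab.loc[genes, "log2fc"] - 2.0).abs().median()
        assert err < 0.3

    def test_contrast_over_missing_coefficient_rejected(self):
        mfits = toy_mfits([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValidationError, match="NR"):
            moderated_test(mfits, "NR-control", spec=DesignSpec())


class TestThresholds:
    def test_enfp_alpha_values(self):
        assert enfp_alpha(400, 4) == 0.01
        assert enfp_alpha(7, 7) == 1.0
        assert enfp_alpha(511, 4) == pytest.approx(4 / 511)

    def test_enfp_alpha_invalid_k(self):
        with pytest.raises(ValidationError):
            enfp_alpha(10, 11)
        with pytest.raises(ValidationError):
            enfp_alpha(10, 0)

    def test_published_fold_p_rows_gate(self):
        table = pd.DataFrame({
            "gene": ["HLA-A", "NFATC1", "g3", "g4"],
            "contrast": "CR-control",
            "log2fc": np.log2([2.17, 0.48, 1.8, 2.5]),
            "fold": [2.17, 0.48, 1.8, 2.5],
            "t": 0.0,
            "p": [0.0007, 0.0002, 0.001, 0.02],
            "significant": False,
        })
        assert call_significant(table, 2.0, 0.01) == {"HLA-A", "NFATC1"}

    def test_everything_passes_trivial_gate(self):
        table = pd.DataFrame({"gene": ["a", "b"], "fold": [1.0, 3.0],
                              "p": [0.5, 0.9]})
        assert call_significant(table, 1.0, 1.0) == {"a", "b"}

    def test_empty_table(self):
        assert call_significant(pd.DataFrame(), 2.0, 0.01) == set()

    @given(st.floats(min_value=1.0, max_value=4.0),
           st.floats(min_value=1e-4, max_value=0.5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_gate_monotonicity(self, fold_hi, alpha):
        rng = np.random.default_rng(10)
        table = pd.DataFrame({
            "gene": [f"g{i}" for i in range(60)],
            "fold": np.exp2(rng.normal(0, 1.5, 60)),
            "p": rng.uniform(0, 1, 60)})
        loose = call_significant(table, 1.0, min(2 * alpha, 1.0))
        strict = call_significant(table, fold_hi, alpha)
        assert strict <= loose


class TestVennPartition:
    def test_hand_example(self):
        regions = venn_partition({"CR": {"a", "b", "c"},
                                  "PR": {"b", "c", "d"},
                                  "NR": {"c", "e"}})
        assert regions["CR∩PR∩NR"] == {"c"}
        assert regions["CR only"] == {"a"}
        assert regions["PR only"] == {"d"}
        assert regions["NR only"] == {"e"}
        assert regions["CR∩PR only"] == {"b"}
        assert sum(len(v) for v in regions.values()) == 5

    def test_identical_sets_single_region(self):
        regions = venn_partition({"CR": {"x", "y"}, "NR": {"x", "y"}})
        assert regions == {"CR∩NR": {"x", "y"}}

    def test_disjoint_sets_only_singletons(self):
        regions = venn_partition({"CR": {"a"}, "NR": {"b"}})
        assert regions == {"CR only": {"a"}, "NR only": {"b"}}

    @given(st.lists(st.sets(st.integers(min_value=0, max_value=12)),
                    min_size=2, max_size=4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_membership_pattern_enumeration(self, sets):
        named = {f"S{i}": {str(x) for x in s} for i, s in enumerate(sets)}
        regions = venn_partition(named)
        # brute force: classify every union element by its membership pattern
        union = set().union(*named.values())
        brute: dict[frozenset, set] = {}
        for g in union:
            pattern = frozenset(n for n, s in named.items() if g in s)
            brute.setdefault(pattern, set()).add(g)
        assert sum(len(v) for v in regions.values()) == len(union)
        got_patterns = {frozenset(r.replace(" only", "").split("∩")): v
                        for r, v in regions.items()}
        assert got_patterns == brute


class TestRtPcr:
    def test_ddct_minus_one_is_twofold(self):
        de = pd.DataFrame({"gene": ["MME"], "log2fc": [1.2]})
        rep = rtpcr_concordance(de, {"MME": -1.0})
        assert rep["fold_pcr"].iloc[0] == pytest.approx(2.0)
        assert rep["concordant"].iloc[0]

    def test_five_gene_panel_fully_concordant(self):
        genes = ["MME", "ITGB2", "MX1", "STAT1", "CCL19"]
        de = pd.DataFrame({"gene": genes,
                           "log2fc": [1.0, -1.5, 2.0, 1.2, -0.8]})
        pcr = {g: -np.sign(fc) for g, fc in zip(de["gene"], de["log2fc"])}
        rep = rtpcr_concordance(de, pcr)
        assert rep.attrs["concordance"] == 1.0

    def test_four_of_five(self):
        de = pd.DataFrame({"gene": list("abcde"),
                           "log2fc": [1.0, 1.0, 1.0, 1.0, 1.0]})
        pcr = {"a": -1, "b": -1, "c": -1, "d": -1, "e": 1}
        assert rtpcr_concordance(de, pcr).attrs["concordance"] == 0.8

    def test_no_overlap_rejected(self):
        de = pd.DataFrame({"gene": ["a"], "log2fc": [1.0]})
        with pytest.raises(ValidationError, match="shared"):
            rtpcr_concordance(de, {"z": 1.0})
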
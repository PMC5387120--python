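"""Woolf effects, fixed/random-effects pooling and heterogeneity statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hmoxmeta as hm

log_ors = st.floats(min_value=-3, max_value=3, allow_nan=False)
variances = st.floats(min_value=1e-3, max_value=5.0, allow_nan=False)


def make_effects(pairs):
    return [hm.EffectEstimate(study_id=f"s{i}", log_or=t, var=v)
            for i, (t, v) in enumerate(pairs)]


effect_lists = st.lists(st.tuples(log_ors, variances), min_size=1, max_size=6).map(make_effects)


class TestWoolfEffect:
    def test_du_genotype_effect(self):
        # cross-product and reciprocal-sum formulas on the published counts
        e = hm.woolf_effect(hm.FourfoldTable(26, 38, 12, 44), study_id="Du")
        assert e.or_point == pytest.approx(2.5088, abs=1e-3)
        assert e.var == pytest.approx(0.17084, abs=1e-4)
        assert not e.corrected

    def test_symmetric_table_gives_unit_or(self):
        e = hm.woolf_effect(hm.FourfoldTable(10, 10, 10, 10))
        assert e.log_or == pytest.approx(0.0)
        assert e.ci_low < 1.0 < e.ci_high

    def test_zero_cell_triggers_continuity_correction(self):
        e = hm.woolf_effect(hm.FourfoldTable(1, 0, 1, 1))
        # corrected cells (1.5, 0.5, 1.5, 1.5): OR = 3
        assert e.corrected
        assert e.or_point == pytest.approx(3.0)

    def test_all_zero_table_rejected(self):
        with pytest.raises(hm.DegenerateTableError):
            hm.woolf_effect(hm.FourfoldTable(0, 0, 0, 0))

    def test_ci_brackets_point_estimate(self):
        e = hm.woolf_effect(hm.FourfoldTable(30, 98, 12, 100))
        assert e.ci_low < e.or_point < e.ci_high
        assert e.ci_low == pytest.approx(math.exp(e.log_or - hm.Z_975 * e.se))


class TestFixedEffect:
    def test_single_study_returns_that_estimate(self):
        e = make_effects([(0.5, 0.1)])
        r = hm.pool_fixed_iv(e)
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.q == 0.0 and r.df == 0
        assert r.heterogeneity.band is None

    def test_asian_l_allele_subgroup(self, studies, by_id):
        # tau-squared truncates to 0 here, so fixed effect equals the
        # published random-effects subgroup value
        asian = by_id("Du", "Fu", "Ma", "Yamada")
        r = hm.pool_fixed_iv(hm.study_effects(asian, hm.Comparison.ALLELE_L))
        assert round(r.pooled_or, 2) == 2.23
        assert (round(r.ci_low, 2), round(r.ci_high, 2)) == (1.68, 2.95)

    def test_two_opposite_studies_cancel(self):
        effects = make_effects([(0.7, 0.2), (-0.7, 0.2)])
        r = hm.pool_fixed_iv(effects)
        assert r.pooled_log_or == pytest.approx(0.0)
        # brute force: Q = sum w_i (theta_i - 0)^2 = 2 * 0.49 / 0.2
        assert r.q == pytest.approx(2 * 0.49 / 0.2)

    @settings(derandomize=True, max_examples=80)
    @given(effects=effect_lists)
    def test_matches_brute_force_weighted_mean(self, effects):
        # independent oracle: plain-Python loops, no shared code path
        r = hm.pool_fixed_iv(effects)
        num = math.fsum(e.log_or / e.var for e in effects)
        den = math.fsum(1.0 / e.var for e in effects)
        assert r.pooled_log_or == pytest.approx(num / den, rel=1e-9, abs=1e-12)
        assert r.pooled_se == pytest.approx(1.0 / math.sqrt(den), rel=1e-9)
        assert sum(w for _, w in r.weights) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hm.pool_fixed_iv([])


class TestRandomEffectsDL:
    def test_l_allele_overall(self, allele_effects_l):
        r = hm.pool_random_dl(allele_effects_l)
        assert round(r.pooled_or, 2) == 2.02
        assert (round(r.ci_low, 2), round(r.ci_high, 2)) == (1.31, 3.11)
        assert r.p_value == pytest.approx(0.001, abs=5e-4)

    def test_genotype_overall(self, genotype_effects):
        r = hm.pool_random_dl(genotype_effects)
        assert round(r.pooled_or, 2) == 1.82
        assert (round(r.ci_low, 2), round(r.ci_high, 2)) == (1.28, 2.61)

    @settings(derandomize=True, max_examples=80)
    @given(effects=effect_lists)
    def test_tau_squared_matches_moment_formula(self, effects):
        r = hm.pool_random_dl(effects)
        w = [1.0 / e.var for e in effects]
        sw = math.fsum(w)
        mu = math.fsum(wi * e.log_or for wi, e in zip(w, effects)) / sw
        q = math.fsum(wi * (e.log_or - mu) ** 2 for wi, e in zip(w, effects))
        df = len(effects) - 1
        if df == 0:
            assert r.tau_squared == 0.0
            return
        c = sw - math.fsum(wi * wi for wi in w) / sw
        assert r.tau_squared == pytest.approx(max(0.0, (q - df) / c), rel=1e-9, abs=1e-12)

    @settings(derandomize=True, max_examples=80)
    @given(effects=effect_lists)
    def test_re_se_never_below_fe_se(self, effects):
        fe = hm.pool_fixed_iv(effects)
        re = hm.pool_random_dl(effects)
        assert re.pooled_se >= fe.pooled_se - 1e-12

    def test_homogeneous_effects_collapse_to_fixed(self):
        # identical estimates: Q = 0 <= df, so tau2 truncates to 0
        effects = make_effects([(0.4, 0.2)] * 4)
        fe, re = hm.pool_fixed_iv(effects), hm.pool_random_dl(effects)
        assert re.tau_squared == 0.0
        assert re.pooled_log_or == pytest.approx(fe.pooled_log_or)
        assert re.pooled_se == pytest.approx(fe.pooled_se)

    @settings(derandomize=True, max_examples=40)
    @given(effects=effect_lists, seed=st.integers(0, 2**16))
    def test_reordering_studies_changes_nothing(self, effects, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(effects))
        shuffled = [effects[i] for i in perm]
        a, b = hm.pool_random_dl(effects), hm.pool_random_dl(shuffled)
        assert a.pooled_log_or == pytest.approx(b.pooled_log_or, rel=1e-12, abs=1e-12)
        assert a.q == pytest.approx(b.q, rel=1e-9, abs=1e-12)
        assert dict(a.weights) == pytest.approx(dict(b.weights))

    def test_cross_checked_against_statsmodels(self, genotype_effects):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        effect = np.array([e.log_or for e in genotype_effects])
        var = np.array([e.var for e in genotype_effects])
        res = sm_meta.combine_effects(effect, var, method_re="dl")
        frame = res.summary_frame()
        fe, re = hm.pool_fixed_iv(genotype_effects), hm.pool_random_dl(genotype_effects)
        assert fe.pooled_log_or == pytest.approx(frame.loc["fixed effect", "eff"], rel=1e-6)
        assert re.pooled_log_or == pytest.approx(frame.loc["random effect", "eff"], rel=1e-6)
        assert re.tau_squared == pytest.approx(res.tau2, rel=1e-6)


class TestHeterogeneity:
    def test_l_allele_comparison(self, allele_effects_l):
        het = hm.heterogeneity(allele_effects_l)
        assert round(het.i_squared) == 52
        assert round(het.p_q, 2) == 0.08
        assert het.band is hm.HeterogeneityBand.MODERATE

    def test_genotype_comparison(self, genotype_effects):
        het = hm.heterogeneity(genotype_effects)
        assert round(het.i_squared) == 37
        assert round(het.p_q, 2) == 0.14

    def test_identical_effects_have_no_heterogeneity(self):
        het = hm.heterogeneity(make_effects([(0.3, 0.1)] * 3))
        assert het.q == pytest.approx(0.0)
        assert het.i_squared == 0.0
        assert het.band is hm.HeterogeneityBand.LOW

    def test_single_study_flagged_undefined(self):
        het = hm.heterogeneity(make_effects([(0.3, 0.1)]))
        assert het.q == 0.0 and het.p_q == 1.0 and het.band is None
        assert not het.meaningful

    def test_i_squared_arithmetic(self):
        # two studies of equal variance with log ORs +-1: Q = 2/v, df = 1
        het = hm.heterogeneity(make_effects([(1.0, 0.4), (-1.0, 0.4)]))
        assert het.q == pytest.approx(5.0)
        assert het.i_squared == pytest.approx((5.0 - 1.0) / 5.0 * 100)


class TestModelSelection:
    @pytest.mark.parametrize("p_q, expected", [
        (0.32, hm.Model.FIXED_IV),   # M vs S+L comparison lacks heterogeneity
        (0.08, hm.Model.RANDOM_DL),  # L vs S+M comparison shows it
        (0.10, hm.Model.RANDOM_DL),  # boundary goes to random effects
    ])
    def test_threshold_rule(self, p_q, expected):
        assert hm.select_model(p_q) is expected

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            hm.select_model(1.5)

    def test_rule_based_mode_picks_fixed_when_homogeneous(self):
        effects = make_effects([(0.4, 0.2), (0.45, 0.25), (0.38, 0.3)])
        assert hm.pool(effects, model="rule_based").model is hm.Model.FIXED_IV
        assert hm.pool(effects, model="dl_default").model is hm.Model.RANDOM_DL

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            hm.pool(make_effects([(0.1, 0.1)]), model="bayes")
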
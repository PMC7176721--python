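import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lfqenrich import (
    AnalysisConfig,
    Fraction,
    ModerationFit,
    Prep,
    Status,
    adaptive_bh,
    estimate_pi0,
    fit_variance_prior,
    fold_change_gate,
    group_stats,
    moderated_t,
    run_comparison,
)
from lfqenrich.preprocess import ComparisonFrame


def make_frame(plus, control):
    plus = np.atleast_2d(np.asarray(plus, float))
    control = np.atleast_2d(np.asarray(control, float))
    values = np.hstack([plus, control])
    n = values.shape[0]
    frame = ComparisonFrame(
        control=Fraction.TOTAL,
        prep=Prep.GEL,
        protein_ids=[f"P{i + 1}" for i in range(n)],
        status=np.array([Status.TESTED] * n, dtype=object),
        values=values,
        mask=np.ones_like(values, bool),
        n_plus=plus.shape[1],
        n_control=control.shape[1],
    )
    frame.tested_values = values.copy()
    return frame


class TestGroupStats:
    def test_hand_computed_example(self):
        df = group_stats(make_frame([1, 2, 3], [3, 4, 5]))
        assert df.loc[0, "log2fc"] == pytest.approx(-2.0)
        assert df.loc[0, "s_g_sq"] == pytest.approx(1.0)
        assert df.loc[0, "d_g"] == 4

    def test_identical_groups_zero_fc(self):
        df = group_stats(make_frame([2, 3, 4], [2, 3, 4]))
        assert df.loc[0, "log2fc"] == 0.0

    def test_constant_groups_zero_variance(self):
        df = group_stats(make_frame([2, 2], [5, 5]))
        assert df.loc[0, "s_g_sq"] == 0.0
        assert df.loc[0, "log2fc"] == -3.0

    def test_single_replicate_rejected(self):
        frame = make_frame([[1], [2]], [[3], [4]])
        with pytest.raises(ValueError, match="two replicates"):
            group_stats(frame)


class TestFoldChangeGate:
    def test_threshold_arithmetic(self, config):
        passed = fold_change_gate(np.array([0.2, -1.0, 0.38]), config)
        # log2(1.3) ~ 0.3785: 0.2 fails, |−1| passes, 0.38 passes
        assert list(passed) == [False, True, True]

    def test_near_unit_threshold_is_vacuous(self):
        # as the raw threshold approaches 1 the gate passes any real change
        cfg = AnalysisConfig(fc_threshold_raw=1.0 + 1e-9)
        assert fold_change_gate(np.array([0.001, -0.001, 2.0]), cfg).all()


class TestVariancePrior:
    def test_identical_variances_give_infinite_d0(self):
        from scipy.special import digamma

        fit = fit_variance_prior(np.full(10, 0.5), d_g=4)
        assert np.isinf(fit.d0)
        # zero spread -> infinite prior df; the scale is the log-bias-corrected
        # common variance exp(log 0.5 - digamma(2) + log 2)
        expected = 0.5 * 2.0 / np.exp(digamma(2.0))
        assert fit.s0_sq == pytest.approx(expected, rel=1e-12)

    def test_two_different_variances_give_finite_d0(self):
        fit = fit_variance_prior(np.array([0.01, 1.0]), d_g=4)
        assert 0 < fit.d0 < np.inf

    def test_parameter_recovery_from_scaled_f_sample(self):
        # s2 ~ s0^2 * chi2_dg/dg * (d0 / chi2_d0): the scaled-F model
        rng = np.random.default_rng(11)
        d0, s0_sq, m, d_g = 4.0, 1.0, 5000, 4
        sigma_sq = s0_sq * d0 / rng.chisquare(d0, m)
        s2 = sigma_sq * rng.chisquare(d_g, m) / d_g
        fit = fit_variance_prior(s2, d_g)
        assert fit.d0 == pytest.approx(d0, rel=0.2)
        assert fit.s0_sq == pytest.approx(s0_sq, rel=0.1)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_variance_prior(np.zeros(5), d_g=4)


class TestModeratedT:
    def test_hand_computed_example(self):
        fit = ModerationFit(d0=4.0, s0_sq=1.0, s_g_sq=np.array([1.0]), d_g=4.0)
        t, df, p = moderated_t(
            np.array([-2.0]), np.array([1.0]), 4, 3, 3, fit
        )
        assert t[0] == pytest.approx(-2.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert df == 8.0

    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (40, 4))
        b = rng.normal(0.3, 1, (40, 4))
        frame = make_frame(a, b)
        df = group_stats(frame)
        fit = ModerationFit(d0=0.0, s0_sq=1.0, s_g_sq=df["s_g_sq"].to_numpy(),
                            d_g=6.0)
        t, dof, p = moderated_t(df["log2fc"].to_numpy(), df["s_g_sq"].to_numpy(),
                                6, 4, 4, fit)
        ref = stats.ttest_ind(a, b, axis=1)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(p, ref.pvalue, atol=1e-10)
        assert dof == 6.0

    def test_d0_infinite_equals_z_test(self):
        fit = ModerationFit(d0=np.inf, s0_sq=0.5, s_g_sq=np.array([2.0]),
                            d_g=4.0)
        fc = np.array([0.8])
        t, dof, p = moderated_t(fc, np.array([2.0]), 4, 3, 3, fit)
        se = np.sqrt(0.5 * (1 / 3 + 1 / 3))
        assert t[0] == pytest.approx(0.8 / se, abs=1e-12)
        assert np.isinf(dof)
        assert p[0] == pytest.approx(2 * stats.norm.sf(0.8 / se), abs=1e-12)


class TestPi0:
    def test_saturated_nulls(self):
        assert estimate_pi0(np.ones(10)) == 1.0

    def test_mean_based_arithmetic(self):
        assert estimate_pi0(np.array([0.1, 0.2, 0.9])) == pytest.approx(0.8)

    def test_uniform_p_values_estimate_near_one(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-12, 1, 10000)
        assert estimate_pi0(p, "mean2x") == pytest.approx(1.0, abs=0.05)
        assert estimate_pi0(p, "storey") == pytest.approx(1.0, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_pi0(np.array([]))


def _brute_force_bh(p, pi0=1.0):
    """Independent step-up oracle: adjusted p by direct definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        j = rank_pos + 1
        candidates = [
            min(1.0, pi0 * m * p[order[k]] / (k + 1))
            for k in range(rank_pos, m)
        ]
        adj[idx] = min(candidates)
    return adj


class TestAdaptiveBH:
    def test_hand_computed_example(self):
        out = adaptive_bh(np.array([0.01, 0.02, 0.04]), pi0=1.0)
        np.testing.assert_allclose(out, [0.03, 0.03, 0.04])

    def test_single_p_identity(self):
        assert adaptive_bh(np.array([0.2]), pi0=1.0)[0] == pytest.approx(0.2)

    def test_matches_statsmodels_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 200)
        mine = adaptive_bh(p, pi0=1.0)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20),
        st.floats(0.05, 1.0),
    )
    def test_matches_brute_force_with_pi0(self, p_list, pi0):
        p = np.array(p_list)
        np.testing.assert_allclose(
            adaptive_bh(p, pi0), _brute_force_bh(p, pi0), atol=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
    def test_monotone_and_bounded(self, p_list):
        p = np.array(p_list)
        adj = adaptive_bh(p, 0.7)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # ties share an adjusted value
        p2 = np.array([0.3, 0.3, 0.8])
        a2 = adaptive_bh(p2, 1.0)
        assert a2[0] == a2[1]


class TestRunComparison:
    def test_single_large_effect_among_nulls(self, config):
        # heterogeneous nulls: the high-variance ones drift past the
        # fold-change gate but carry large p-values, so only the constructed
        # separation reaches significance
        rng = np.random.default_rng(21)
        sd = np.full(120, 0.15)
        sd[100:] = 1.2
        plus = 20 + rng.standard_normal((120, 5)) * sd[:, None]
        ctl = 20 + rng.standard_normal((120, 5)) * sd[:, None]
        plus[0] += 5.0  # one strongly enriched protein
        res = run_comparison(make_frame(plus, ctl), config)
        called = res.table[res.table.significant_enriched]
        assert list(called.protein_id) == ["P1"]

    def test_pure_null_frame_rarely_calls(self, config):
        calls = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            plus = rng.normal(20, 0.2, (200, 5))
            ctl = rng.normal(20, 0.2, (200, 5))
            res = run_comparison(make_frame(plus, ctl), config)
            calls += int(res.table.significant_enriched.sum() > 0)
        assert calls <= 2  # >= 80% of runs make zero calls

    def test_everything_gated_out_means_no_tests(self, config):
        rng = np.random.default_rng(3)
        base = rng.normal(20, 0.01, (20, 5))
        with pytest.warns(UserWarning, match="fold-change gate"):
            res = run_comparison(make_frame(base, base + 0.01), config)
        assert (res.table.status == "fc_filtered").all()
        assert res.table.p.isna().all()

    def test_result_invariants(self, config):
        rng = np.random.default_rng(4)
        plus = rng.normal(20, 0.3, (150, 5))
        ctl = rng.normal(20, 0.3, (150, 5))
        plus[:20] += rng.uniform(1, 2, (20, 1))
        res = run_comparison(make_frame(plus, ctl), config)
        t = res.table
        sig = t[t.significant_enriched]
        assert (sig.status == "tested").all()
        assert (sig.p_adj < config.fdr_level).all()
        assert (sig.log2fc >= config.log2_fc_threshold - 1e-9).all()
        tested = t[t.p.notna()]
        # p_adj >= pi0 * p and monotone in p
        assert (tested.p_adj >= res.meta["pi0"] * tested.p - 1e-12).all()
        srt = tested.sort_values("p")
        assert np.all(np.diff(srt.p_adj) >= -1e-12)


class TestPowerMonotonicity:
    def test_power_increases_with_effect_and_replicates(self, config):
        def power(effect, n_rep, seed=0):
            rng = np.random.default_rng(seed)
            m, n_alt = 300, 60
            plus = rng.normal(20, 0.35, (m, n_rep))
            ctl = rng.normal(20, 0.35, (m, n_rep))
            plus[:n_alt] += effect
            res = run_comparison(make_frame(plus, ctl), config)
            called = set(res.table[res.table.significant_enriched].protein_id)
            return len(called & {f"P{i + 1}" for i in range(n_alt)}) / n_alt

        assert power(2.0, 5) >= power(0.6, 5)
        assert power(0.8, 8) >= power(0.8, 3)
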
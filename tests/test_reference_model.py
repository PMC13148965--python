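"""Reference replicability model: posterior, MH sampler, posterior-PRP."""

import numpy as np
import pytest
from scipy import stats

from discrep import (
    EffectTable,
    MCMCConfig,
    diagnostics,
    log_posterior,
    mh_sample,
    posterior_prp,
    q_statistic,
)
from discrep.reference_model import (
    NU_HI,
    NU_LO,
    HyperDraw,
    HyperDraws,
    k_of_neg_log10_pmis,
    sample_replicate,
    sample_study_effects,
)
from discrep.distinguishability import k_from_pmis
from tests.conftest import random_table

FAST = MCMCConfig(iterations=2000, burn_in_rate=0.05, seed=7)


class TestKInterpolation:
    def test_matches_direct_inversion(self):
        for nu in np.linspace(NU_LO + 1e-6, NU_HI - 1e-6, 17):
            assert k_of_neg_log10_pmis(nu) == pytest.approx(
                k_from_pmis(10.0 ** (-nu)), rel=1e-5
            )

    def test_hyperdraw_fills_consistent_k(self):
        d = HyperDraw(beta_bar=0.1, neg_log10_pmis=2.0)
        assert d.k == pytest.approx(k_from_pmis(0.01), rel=1e-5)


class TestLogPosterior:
    def test_hand_summed_normal_densities(self, two_study_table):
        state = HyperDraw(beta_bar=0.5, neg_log10_pmis=2.0)
        var = 1.0 + (state.k * 0.5) ** 2
        expected = stats.norm.logpdf(0.0, 0.5, np.sqrt(var)) + stats.norm.logpdf(
            1.0, 0.5, np.sqrt(var)
        )
        assert log_posterior(state, two_study_table) == pytest.approx(expected)

    def test_k_zero_collapses_to_sampling_variances(self, small_table):
        state = HyperDraw(beta_bar=0.1, neg_log10_pmis=5.0, k=0.0)
        expected = float(
            np.sum(stats.norm.logpdf(small_table.beta_hat, 0.1, small_table.se))
        )
        assert log_posterior(state, small_table) == pytest.approx(expected)

    @pytest.mark.parametrize("nu", [1.0, 10.5, -2.0])
    def test_outside_prior_support_is_minus_inf(self, nu, small_table):
        state = HyperDraw(beta_bar=0.1, neg_log10_pmis=nu, k=0.1)
        assert log_posterior(state, small_table) == -np.inf


class TestMHSampler:
    def test_seeded_determinism(self, small_table):
        a = mh_sample(small_table, FAST)
        b = mh_sample(small_table, FAST)
        np.testing.assert_array_equal(a.beta_bar, b.beta_bar)
        np.testing.assert_array_equal(a.neg_log10_pmis, b.neg_log10_pmis)

    def test_burn_in_split(self, small_table):
        draws = mh_sample(small_table, FAST)
        assert draws.full_beta_bar.size == 2000
        assert len(draws) == 2000 - 100

    def test_acceptance_ratio_strictly_interior(self, small_table):
        draws = mh_sample(small_table, FAST)
        assert 0.0 < draws.acceptance_ratio < 1.0

    def test_draws_respect_prior_support(self, small_table):
        draws = mh_sample(small_table, FAST)
        assert np.all(draws.neg_log10_pmis >= NU_LO)
        assert np.all(draws.neg_log10_pmis <= NU_HI)
        assert np.all(draws.k >= 0)

    def test_non_finite_data_rejected(self):
        t = EffectTable(beta_hat=[0.1, 0.2], se=[0.1, 0.1])
        object.__setattr__(t, "beta_hat", np.array([np.nan, 0.2]))
        with pytest.raises(ValueError, match="non-finite"):
            mh_sample(t, FAST)

    def test_posterior_concentrates_near_truth(self, rng):
        # strong data: posterior mean of beta_bar close to generating value
        t = random_table(rng, m=30, beta_bar=0.5, k=0.1, se_scale=0.05)
        draws = mh_sample(t, MCMCConfig(iterations=4000, seed=3))
        assert draws.beta_bar.mean() == pytest.approx(0.5, abs=0.05)


class TestConditionals:
    def test_fixed_effect_degenerate_conditional(self, small_table, rng):
        state = HyperDraw(beta_bar=0.2, neg_log10_pmis=5.0, k=0.0)
        betas = sample_study_effects(state, small_table, rng)
        np.testing.assert_allclose(betas, 0.2)

    def test_conditional_moments_by_monte_carlo(self, rng):
        t = EffectTable(beta_hat=[2.0, 2.0], se=[1.0, 1.0])
        state = HyperDraw(beta_bar=1.0, neg_log10_pmis=2.0, k=0.5)
        n = 400_000
        draws = np.array([sample_study_effects(state, t, rng) for _ in range(n // 100)])
        kb2 = 0.25
        mean = (1.0 * 1.0 + kb2 * 2.0) / (1.0 + kb2)
        var = kb2 * 1.0 / (1.0 + kb2)
        assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(var / draws.size))
        assert draws.var() == pytest.approx(var, rel=0.05)

    def test_large_heterogeneity_limit_tracks_observed(self, rng):
        t = EffectTable(beta_hat=[2.0, -1.0], se=[1.0, 1.0])
        state = HyperDraw(beta_bar=1000.0, neg_log10_pmis=NU_LO, k=None)
        kb2 = (state.k * state.beta_bar) ** 2
        mean = (t.variances * state.beta_bar + kb2 * t.beta_hat) / (t.variances + kb2)
        np.testing.assert_allclose(mean, t.beta_hat, rtol=2e-2)

    def test_replicate_structure_and_moments(self, small_table, rng):
        state = HyperDraw(beta_bar=0.1, neg_log10_pmis=3.0)
        betas = np.array([0.1, 0.2, -0.1, 0.05])
        reps = np.array(
            [
                sample_replicate(state, betas, small_table, rng).beta_hat
                for _ in range(4000)
            ]
        )
        rep_table = sample_replicate(state, betas, small_table, rng)
        assert rep_table.m == small_table.m
        np.testing.assert_array_equal(rep_table.se, small_table.se)
        np.testing.assert_allclose(
            reps.mean(axis=0), betas, atol=float(4 * small_table.se.max() / np.sqrt(4000))
        )

    def test_zero_observation_noise_returns_betas(self, rng):
        t = EffectTable(beta_hat=[0.0, 1.0], se=[1e-12, 1e-12])
        state = HyperDraw(beta_bar=0.5, neg_log10_pmis=3.0)
        betas = np.array([0.3, 0.6])
        rep = sample_replicate(state, betas, t, rng)
        np.testing.assert_allclose(rep.beta_hat, betas, atol=1e-10)

    def test_wrong_length_rejected(self, small_table, rng):
        state = HyperDraw(beta_bar=0.1, neg_log10_pmis=3.0)
        with pytest.raises(ValueError, match="length"):
            sample_replicate(state, np.zeros(3), small_table, rng)


class TestPosteriorPRP:
    def test_result_in_unit_interval_and_consistent(self, small_table):
        r = posterior_prp(small_table, q_statistic, FAST)
        assert 0.0 <= r.prp <= 1.0
        assert r.prp == r.count / r.n_used
        assert r.n_used == 1900
        assert r.exceedances.sum() == r.count

    def test_seeded_reproducibility(self, small_table):
        r1 = posterior_prp(small_table, q_statistic, FAST)
        r2 = posterior_prp(small_table, q_statistic, FAST)
        assert r1.prp == r2.prp
        assert r1.count == r2.count

    def test_point_estimate_mode_runs(self, small_table):
        cfg = MCMCConfig(iterations=1000, seed=5, point_estimate_stat=True)
        r = posterior_prp(small_table, q_statistic, cfg)
        assert 0.0 <= r.prp <= 1.0

    def test_scalar_statistic_path_matches_batch(self, small_table):
        from discrep import StatisticSpec

        scalar_only = StatisticSpec(
            name="q-scalar",
            evaluate=lambda beta, se, bb, k: float(
                np.sum((beta - bb) ** 2 / (se**2 + (k * bb) ** 2))
            ),
        )
        cfg = MCMCConfig(iterations=500, seed=11)
        r1 = posterior_prp(small_table, scalar_only, cfg)
        r2 = posterior_prp(small_table, q_statistic, cfg)
        assert r1.prp == r2.prp

    def test_failing_statistic_reports_name(self, small_table):
        from discrep import StatisticSpec

        bad = StatisticSpec(
            name="bad", evaluate=lambda *a: (_ for _ in ()).throw(ValueError("boom"))
        )
        with pytest.raises(RuntimeError, match="bad"):
            posterior_prp(small_table, bad, MCMCConfig(iterations=500, seed=1))


class TestDiagnostics:
    def test_iid_chain_ess_near_n(self, rng):
        n = 4000
        draws = HyperDraws(
            beta_bar=rng.standard_normal(n),
            neg_log10_pmis=rng.uniform(NU_LO, NU_HI, n),
            k=np.full(n, 0.1),
            n_burn=0,
            acceptance_ratio=0.4,
        )
        rep = diagnostics(draws)
        assert rep.ess["beta_bar"] == pytest.approx(n, rel=0.15)
        assert rep.acf["beta_bar"][0] == 1.0

    def test_constant_chain_flagged_minimal(self):
        n = 100
        draws = HyperDraws(
            beta_bar=np.full(n, 0.3),
            neg_log10_pmis=np.full(n, 5.0),
            k=np.full(n, 0.1),
            n_burn=0,
            acceptance_ratio=0.0,
        )
        rep = diagnostics(draws)
        assert rep.ess["beta_bar"] == 1.0

    def test_agrees_with_arviz_on_mh_chain(self, small_table):
        import arviz

        draws = mh_sample(small_table, MCMCConfig(iterations=4000, seed=2))
        rep = diagnostics(draws)
        az = float(arviz.ess(np.asarray(draws.beta_bar)))
        assert rep.ess["beta_bar"] == pytest.approx(az, rel=0.35)

    def test_too_few_draws_rejected(self):
        draws = HyperDraws(
            beta_bar=np.zeros(5),
            neg_log10_pmis=np.zeros(5),
            k=np.zeros(5),
            n_burn=0,
            acceptance_ratio=0.5,
        )
        with pytest.raises(ValueError, match="at least 10"):
            diagnostics(draws)
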
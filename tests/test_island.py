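import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from commdyn.data_io import EnvironmentSeries, PresenceMatrix
from commdyn.island import (
    characteristic_time,
    count_transitions,
    fit_ce,
    fit_ce_counts,
    fit_ce_env,
    transition_probability,
    TransitionCounts,
)
from commdyn.synthetic import TrueCEParams, gen_presence_markov


def _pm(presence, times=None, station="A"):
    presence = np.asarray(presence)
    n, T = presence.shape
    return PresenceMatrix(
        presence=presence,
        taxon_ids=[f"t{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(T)],
        times=np.arange(T, dtype=float) if times is None else np.asarray(times, float),
        station=np.array([station] * T, dtype=object),
    )


class TestTransitionProbability:
    def test_matches_matrix_exponential(self):
        P = transition_probability(0.2, 0.3, 2.0)
        Q = np.array([[-0.2, 0.2], [0.3, -0.3]])
        np.testing.assert_allclose(P, expm(Q * 2.0), atol=1e-12)
        assert abs(P[0, 1] - 0.25285) < 1e-4
        assert abs(P[1, 0] - 0.37927) < 1e-4

    def test_zero_interval_is_identity(self):
        np.testing.assert_allclose(
            transition_probability(0.5, 0.1, 0.0), np.eye(2), atol=1e-15
        )

    def test_long_interval_reaches_stationarity(self):
        c, e = 0.04, 0.01
        P = transition_probability(c, e, 1e9)
        np.testing.assert_allclose(P[0], P[1], atol=1e-12)
        np.testing.assert_allclose(P[0], [e / (c + e), c / (c + e)], atol=1e-12)

    def test_degenerate_chain_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            transition_probability(0.0, 0.0, 1.0)

    @given(
        c=st.floats(1e-6, 10.0),
        e=st.floats(1e-6, 10.0),
        dt=st.floats(0.0, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_rows_sum_to_one(self, c, e, dt):
        P = transition_probability(c, e, dt)
        np.testing.assert_allclose(P.sum(axis=1), [1.0, 1.0], atol=1e-12)
        assert (P >= 0).all()


class TestCountTransitions:
    def test_identical_samples_have_no_turnover(self):
        tc = count_transitions(_pm([[1, 1], [0, 0], [1, 1]]))
        assert tc.n01.sum() == 0 and tc.n10.sum() == 0

    def test_complete_turnover(self):
        tc = count_transitions(_pm([[1, 0], [0, 1], [1, 0], [0, 1]]))
        assert tc.n01[0] == 2 and tc.n10[0] == 2 and tc.n11[0] == 0

    def test_hand_tally(self):
        tc = count_transitions(_pm([[1, 1], [1, 0], [0, 1]]))
        assert (tc.n11[0], tc.n10[0], tc.n01[0], tc.n00[0]) == (1, 1, 1, 0)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            count_transitions(_pm([[1]]))

    def test_counts_partition_taxa(self, irregular_times):
        pm = gen_presence_markov(
            TrueCEParams(S_pool=300), irregular_times, seed=0
        )
        tc = count_transitions(pm)
        np.testing.assert_array_equal(tc.n00 + tc.n01 + tc.n10 + tc.n11, 300)


class TestFitCE:
    def test_symmetric_counts_give_equal_rates(self):
        tc = TransitionCounts(
            dt=[1.0], n00=[50], n01=[25], n10=[25], n11=[50]
        )
        fit = fit_ce_counts(tc, S_pool=150)
        assert fit.c == pytest.approx(fit.e, rel=1e-4)
        assert fit.occupancy_eq == pytest.approx(0.5, abs=1e-4)
        # MLE implies P01 = P10 = 1/3 over the unit interval
        P = transition_probability(fit.c, fit.e, 1.0)
        assert P[0, 1] == pytest.approx(1 / 3, abs=1e-4)

    def test_parameter_recovery_at_study_scale(self, irregular_times):
        pm = gen_presence_markov(
            TrueCEParams(S_pool=10_000, c0=0.01, e0=0.02), irregular_times, seed=2
        )
        fit = fit_ce(pm)
        assert fit.c == pytest.approx(0.01, rel=0.1)
        assert fit.e == pytest.approx(0.02, rel=0.1)
        assert fit.t_char == pytest.approx(1 / 0.03, rel=0.1)
        assert fit.t_char == pytest.approx(1 / (fit.c + fit.e), rel=1e-12)

    def test_boundary_without_colonizations(self):
        fit = fit_ce(_pm([[1, 1, 0], [1, 0, 0]]))
        assert fit.boundary
        assert np.isinf(fit.se_c) and np.isinf(fit.se_e)

    def test_likelihood_splits_over_taxon_subsets(self, irregular_times):
        pm = gen_presence_markov(TrueCEParams(S_pool=400), irregular_times, seed=3)
        half1, half2 = pm.presence[:200], pm.presence[200:]
        from commdyn.island import _loglik_const

        x = np.log([0.013, 0.017])
        total = _loglik_const(x, count_transitions(pm))
        parts = sum(
            _loglik_const(x, count_transitions(_pm(h, times=irregular_times)))
            for h in (half1, half2)
        )
        assert total == pytest.approx(parts, rel=1e-12)


class TestCharacteristicTime:
    def test_stated_value(self):
        assert characteristic_time(0.1, 0.3) == pytest.approx(2.5)

    def test_scaling_and_monotonicity(self):
        assert characteristic_time(0.2, 0.6) == pytest.approx(
            characteristic_time(0.1, 0.3) / 2
        )
        assert characteristic_time(0.1, 0.5) < characteristic_time(0.1, 0.3)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            characteristic_time(0.0, 0.0)


class TestFitCEEnv:
    def test_null_model_matches_constant_fit(self, irregular_times, seasonal_env):
        pm = gen_presence_markov(
            TrueCEParams(S_pool=2000, c0=0.01, e0=0.02),
            irregular_times,
            seasonal_env,
            seed=4,
        )
        const = fit_ce(pm)
        env_fit = fit_ce_env(pm, seasonal_env)
        assert env_fit.logLik >= const.logLik - 1e-6

    def test_beta_recovery_within_three_se(self, irregular_times, seasonal_env):
        pm = gen_presence_markov(
            TrueCEParams(S_pool=10_000, c0=0.01, e0=0.02, beta_c=-0.5, beta_e=-0.3),
            irregular_times,
            seasonal_env,
            seed=5,
        )
        fit = fit_ce_env(pm, seasonal_env)
        assert abs(fit.beta_c + 0.5) < 3 * fit.se[1]
        assert abs(fit.beta_e + 0.3) < 3 * fit.se[3]
        assert fit.lr_pvalue < 1e-6

    def test_contribution_sign_matches_beta(self, irregular_times, seasonal_env):
        pm = gen_presence_markov(
            TrueCEParams(S_pool=3000, c0=0.01, e0=0.02, beta_c=0.4, beta_e=-0.4),
            irregular_times,
            seasonal_env,
            seed=6,
        )
        fit = fit_ce_env(pm, seasonal_env)
        assert np.sign(fit.contribution_c) == np.sign(fit.beta_c)
        assert np.sign(fit.contribution_e) == np.sign(fit.beta_e)

    def test_constant_covariate_rejected(self, irregular_times):
        pm = gen_presence_markov(TrueCEParams(S_pool=50), irregular_times, seed=7)
        env = EnvironmentSeries(
            sample_ids=pm.sample_ids, salinity=np.full(len(irregular_times), 30.0)
        )
        with pytest.raises(ValueError, match="constant"):
            fit_ce_env(pm, env)
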
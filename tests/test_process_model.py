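import numpy as np
import pytest
from scipy import optimize

from commdyn.process_model import (
    CRNModel,
    community_determinism,
    determinism_from_fit,
    drift,
    fit_crn,
    qss_resource,
    simulate_crn,
    taxon_determinism,
)


def _model(n=1, **kw):
    base = dict(
        mu_max=np.full(n, 1.0),
        s_opt=np.full(n, 26.0),
        s_width=np.full(n, 6.0),
        m=np.full(n, 0.2),
        sigma=np.zeros(n),
        p=np.full(n, 1.0 / n),
        K=1.0,
        R_supply=10.0,
        D_R=5.0,
        lam=0.0,
        q=1.0,
    )
    base.update(kw)
    return CRNModel(**base)


class TestDrift:
    def test_no_growth_without_resource(self):
        m = _model(m=np.array([0.3]))
        f, _ = drift(m, np.array([10.0]), R=0.0, s=26.0)
        assert f[0] == pytest.approx(-3.0)

    def test_monod_saturation_limit(self):
        m = _model()
        f, _ = drift(m, np.array([1.0]), R=1e12, s=26.0)
        assert f[0] == pytest.approx(1.0 - 0.2, rel=1e-6)

    def test_hand_value(self):
        # N=10, mu=1, K=1, R=1 (Monod 0.5), phi=1, m=0.2 -> f = 10*(0.5-0.2) = 3
        m = _model()
        f, _ = drift(m, np.array([10.0]), R=1.0, s=26.0)
        assert f[0] == pytest.approx(3.0)

    def test_salinity_filter_reduces_growth(self):
        m = _model()
        f_opt, _ = drift(m, np.array([5.0]), R=5.0, s=26.0)
        f_off, _ = drift(m, np.array([5.0]), R=5.0, s=40.0)
        assert f_off[0] < f_opt[0]

    def test_qss_resource_is_drift_root(self):
        m = _model(n=3, s_opt=np.array([20.0, 26.0, 30.0]))
        N = np.array([3.0, 5.0, 2.0])
        R_star = qss_resource(m, N, s=25.0)
        assert drift(m, N, R_star, 25.0)[1] == pytest.approx(0.0, abs=1e-8)


class TestSimulate:
    def test_deterministic_limit_converges_with_step(self, irregular_times, seasonal_salinity):
        m = _model(mu_max=np.array([0.03]), m=np.array([0.01]))
        N1, _ = simulate_crn(m, irregular_times, seasonal_salinity, dt_int=0.5, seed=0)
        N2, _ = simulate_crn(m, irregular_times, seasonal_salinity, dt_int=0.25, seed=1)
        assert abs(N1[0, -1] - N2[0, -1]) / N2[0, -1] < 0.01

    def test_driftless_diffusion_is_martingale(self):
        times = np.arange(0.0, 300.0, 30.0)
        m = _model(mu_max=np.array([0.0]), m=np.array([0.0]), sigma=np.array([0.5]))
        ends = [
            simulate_crn(m, times, None, dt_int=0.5, seed=s, N0=np.array([100.0]),
                         burn_in=0.0)[0][0, -1]
            for s in range(500)
        ]
        se = np.std(ends) / np.sqrt(len(ends))
        assert abs(np.mean(ends) - 100.0) < 3 * se

    def test_single_taxon_reaches_monod_equilibrium(self):
        # equilibrium: mu*M(R*)=m with resource balance at N*
        m = _model(mu_max=np.array([0.4]), m=np.array([0.1]), D_R=2.0)
        times = np.arange(0.0, 2000.0, 20.0)
        N, R = simulate_crn(m, times, np.full(len(times), 26.0), dt_int=0.1, seed=0,
                            burn_in=0.0, N0=np.array([1.0]))

        def balance(n):
            r = qss_resource(m, np.array([n]), 26.0)
            return 0.4 * r / (1 + r) - 0.1

        N_star = optimize.brentq(balance, 1e-3, 1e6)
        assert N[0, -1] == pytest.approx(N_star, rel=1e-3)

    def test_reproducible_under_seed(self, irregular_times, seasonal_salinity):
        m = _model(sigma=np.array([0.2]))
        a = simulate_crn(m, irregular_times, seasonal_salinity, seed=5)[0]
        b = simulate_crn(m, irregular_times, seasonal_salinity, seed=5)[0]
        np.testing.assert_array_equal(a, b)

    def test_bad_step_rejected(self, irregular_times, seasonal_salinity):
        with pytest.raises(ValueError, match="dt_int"):
            simulate_crn(_model(), irregular_times, seasonal_salinity, dt_int=100.0)


class TestTaxonDeterminism:
    def test_limits(self):
        assert taxon_determinism(f=0.1, sigma=0.0, x=0.5, dt=30.0) == 100.0
        assert taxon_determinism(f=0.0, sigma=0.2, x=0.5, dt=30.0) == 0.0
        assert taxon_determinism(f=0.0, sigma=0.0, x=0.5, dt=30.0) == 0.0

    def test_equal_parts_give_fifty(self):
        # choose sigma so (f dt)^2 == sigma^2 x dt
        f, x, dt = 0.01, 0.2, 25.0
        sigma = np.sqrt((f * dt) ** 2 / (x * dt))
        assert taxon_determinism(f, sigma, x, dt) == pytest.approx(50.0)

    def test_monotone_in_drift_and_noise(self):
        d_lo = taxon_determinism(0.01, 0.1, 0.3, 30.0)
        d_hi = taxon_determinism(0.02, 0.1, 0.3, 30.0)
        assert d_hi > d_lo
        assert taxon_determinism(0.01, 0.2, 0.3, 30.0) < d_lo


class TestCommunityDeterminism:
    def test_uniform_values_pass_through(self):
        D = np.full((4, 6), 40.0)
        x = np.random.default_rng(0).dirichlet(np.ones(4), size=6).T
        res = community_determinism(D, x)
        assert res.D_mean_unweighted == pytest.approx(40.0)
        assert res.D_mean_weighted == pytest.approx(40.0)

    def test_equal_abundances_make_weights_irrelevant(self):
        rng = np.random.default_rng(1)
        D = rng.uniform(0, 100, size=(5, 8))
        x = np.full((5, 8), 0.2)
        res = community_determinism(D, x)
        np.testing.assert_allclose(res.D_weighted, res.D_unweighted)

    def test_hand_weighted_example(self):
        D = np.array([[80.0], [20.0]])
        x = np.array([[0.75], [0.25]])
        res = community_determinism(D, x)
        assert res.D_weighted[0] == pytest.approx(65.0)
        assert res.D_unweighted[0] == pytest.approx(50.0)

    def test_empty_times_flagged(self):
        D = np.array([[50.0, 60.0]])
        x = np.array([[0.0, 1.0]])
        res = community_determinism(D, x)
        assert res.flagged_times == [0]
        assert res.D_mean_unweighted == pytest.approx(60.0)


class TestFitCRN:
    def test_noiseless_sigma_estimate_is_tiny(self, irregular_times, seasonal_salinity):
        n = 8
        m = _model(
            n=n,
            mu_max=np.full(n, 0.02),
            s_opt=np.linspace(20, 32, n),
            s_width=np.full(n, 8.0),
            m=np.full(n, 0.008),
            lam=1e-3,
        )
        N, _ = simulate_crn(m, irregular_times, seasonal_salinity, dt_int=0.25,
                            seed=1, burn_in=730.0)
        x = N / N.sum(axis=0)
        fit = fit_crn(x, seasonal_salinity, top_k=n, times=irregular_times)
        assert fit.sigma.max() < 1e-3

    def test_niche_optimum_recovery_with_measured_resource(
        self, irregular_times, seasonal_salinity
    ):
        n = 5
        true_opt = np.linspace(22, 30, n)
        m = _model(
            n=n,
            mu_max=np.full(n, 0.02),
            s_opt=true_opt,
            s_width=np.full(n, 8.0),
            m=np.full(n, 0.008),
            sigma=np.full(n, 0.05),
            lam=1e-3,
        )
        ids = [f"t{i}" for i in range(n)]
        N, R = simulate_crn(m, irregular_times, seasonal_salinity, dt_int=0.25,
                            seed=2, burn_in=730.0)
        fit = fit_crn(N, seasonal_salinity, top_k=n, times=irregular_times,
                      frame="absolute", resource=R, taxon_ids=ids)
        pos = {t: j for j, t in enumerate(fit.taxon_ids)}
        err = np.array([fit.s_opt[pos[ids[i]]] - true_opt[i] for i in range(n)])
        occ = (N > 1).mean(axis=1)
        assert np.mean(np.abs(err[occ > 0.5])) < 2.0

    def test_sparse_taxa_are_skipped(self, irregular_times, seasonal_salinity):
        x = np.vstack(
            [
                np.full(len(irregular_times), 0.5),
                np.full(len(irregular_times), 0.5),
                np.zeros(len(irregular_times)),
            ]
        )
        x[2, 3] = 1e-4
        fit = fit_crn(x, seasonal_salinity, top_k=3, times=irregular_times)
        assert len(fit.skipped) == 1

    def test_shuffled_order_fits_worse(self, irregular_times, seasonal_salinity):
        """Temporal signal: permuting samples degrades the drift fit."""
        n = 6
        m = _model(
            n=n,
            mu_max=np.full(n, 0.02),
            s_opt=np.linspace(20, 32, n),
            s_width=np.full(n, 8.0),
            m=np.full(n, 0.008),
            lam=1e-3,
        )
        N, _ = simulate_crn(m, irregular_times, seasonal_salinity, dt_int=0.25,
                            seed=3, burn_in=730.0)
        x = N / N.sum(axis=0)
        worse = 0
        n_runs = 20
        fit = fit_crn(x, seasonal_salinity, top_k=n, times=irregular_times)
        for k in range(n_runs):
            perm = np.random.default_rng(k).permutation(x.shape[1])
            fit_p = fit_crn(x[:, perm], seasonal_salinity[perm], top_k=n,
                            times=irregular_times)
            worse += fit_p.sigma.mean() > fit.sigma.mean()
        assert worse >= 19

    def test_determinism_bounds_and_shapes(self, irregular_times, seasonal_salinity):
        n = 6
        m = _model(
            n=n,
            mu_max=np.full(n, 0.02),
            s_opt=np.linspace(20, 32, n),
            s_width=np.full(n, 8.0),
            m=np.full(n, 0.008),
            sigma=np.full(n, 0.1),
            lam=1e-3,
        )
        N, _ = simulate_crn(m, irregular_times, seasonal_salinity, dt_int=0.25,
                            seed=4, burn_in=365.0)
        x = N / N.sum(axis=0)
        fit = fit_crn(x, seasonal_salinity, top_k=n, times=irregular_times)
        det = determinism_from_fit(fit)
        assert det.D.shape == (n, len(irregular_times) - 1)
        ok = np.isfinite(det.D)
        assert (det.D[ok] >= 0).all() and (det.D[ok] <= 100).all()
        assert 0 <= det.D_mean_weighted <= 100
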
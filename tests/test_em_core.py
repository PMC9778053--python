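import numpy as np
import pytest
from scipy.optimize import minimize

from embai import (
    DataError,
    PriorConfig,
    WhitenedData,
    compute_grm,
    fit_emba,
    fit_embai,
    fit_embayesa,
    make_scenario_one_qtn,
    predict_gebv,
    simulate_genotypes,
    simulate_phenotype,
)
from embai.em_core import (
    e_step_sigma_k,
    m_step_alpha,
    m_step_gamma_k,
    m_step_sigma2,
)
from _helpers import assert_ascent


class TestUpdateRules:
    @pytest.mark.parametrize(
        "gamma_k,scale,nu,expected",
        [(2.0, 1.0, 4.0, 1.0), (0.0, 0.0, 3.0, 0.0), (0.0, 0.02, 3.0, 0.005)],
    )
    def test_e_step_values(self, gamma_k, scale, nu, expected):
        prior = PriorConfig(nu=nu, scale=max(scale, 0.0))
        assert e_step_sigma_k(gamma_k, prior) == pytest.approx(expected)

    def test_gamma_update_orthogonal_residual(self):
        z = np.array([1.0, -1.0, 0.0])
        r = np.array([1.0, 1.0, 5.0])  # orthogonal to z
        assert m_step_gamma_k(r, z, sigma_k2=1.0, sigma2=1.0) == 0.0

    def test_gamma_update_no_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(20)
        r = rng.standard_normal(20)
        ols = (z @ r) / (z @ z)
        assert m_step_gamma_k(r, z, sigma_k2=1e12, sigma2=1e-12) == pytest.approx(ols)

    def test_alpha_update_is_partial_ols(self):
        w = np.array([1.0, 1.0, 1.0, 1.0])
        y = np.array([3.0, 3.0, 3.0, 3.0])
        assert m_step_alpha(y, w) == pytest.approx(3.0)
        assert m_step_alpha(np.array([1.0, -1.0, 1.0, -1.0]), w) == 0.0
        with pytest.raises(DataError):
            m_step_alpha(y, np.zeros(4))

    @pytest.mark.parametrize(
        "resid,n,expected", [([1.0, -1.0], 2, 1.0), ([2.0] * 4, 4, 4.0)]
    )
    def test_sigma2_update(self, resid, n, expected):
        assert m_step_sigma2(np.array(resid), n) == pytest.approx(expected)

    def test_sigma2_floor(self):
        assert m_step_sigma2(np.zeros(3), 3) == 1e-12


def _marginal_objective(theta, y, W, Z, prior):
    """Scaled-t marginal log-posterior; sigma2 passed on log scale."""
    c, q = W.shape[1], Z.shape[1]
    alpha, gamma, log_s2 = theta[:c], theta[c : c + q], theta[-1]
    s2 = np.exp(log_s2)
    r = y - W @ alpha - Z @ gamma
    n = y.size
    return (
        -0.5 * n * log_s2
        - (r @ r) / (2 * s2)
        - 0.5 * (prior.nu + 1) * np.sum(np.log(gamma**2 + prior.scale))
    )


class TestFitEmBayesA:
    def test_null_signal_shrinks_all_effects(self):
        rng = np.random.default_rng(1)
        n, q = 60, 20
        W = np.ones((n, 1))
        Z = rng.integers(0, 3, (n, q)).astype(float)
        y = W[:, 0] * 5.0  # exactly W alpha, no marker signal, no noise
        fit = fit_embayesa(WhitenedData(y, W, Z), PriorConfig(scale=1e-4))
        assert np.max(np.abs(fit.gamma)) < 1e-3
        assert_ascent(fit.log_posterior_trace)

    def test_qtn_effect_dominates(self):
        """The causal marker carries the largest |gamma_hat| in every rep."""
        wins = 0
        for seed in range(10):
            g = simulate_genotypes(400, 800, seed=500 + seed)
            scen = make_scenario_one_qtn(g, background_multiplier=0.0, seed=600 + seed)
            ds = simulate_phenotype(g, scen)
            fit = fit_emba(ds.phenotype, np.ones((400, 1)), g)
            wins += int(np.argmax(np.abs(fit.gamma)) == 97)
            assert_ascent(fit.log_posterior_trace)
        assert wins >= 9

    def test_fixed_point_matches_brute_force_oracle(self, tight_prior):
        """The EM fixed point maximizes the marginal log-posterior: compare
        against generic numerical optimization on a tiny instance."""
        rng = np.random.default_rng(11)
        n, q = 8, 2
        W = np.ones((n, 1))
        Z = rng.integers(0, 3, (n, q)).astype(float)
        y = 2.0 + Z @ np.array([1.0, -0.6]) + 0.3 * rng.standard_normal(n)
        prior = tight_prior
        fit = fit_embayesa(WhitenedData(y, W, Z), prior)

        best = None
        for start_scale in [0.0, 0.5, 1.0]:
            theta0 = np.concatenate(
                [[y.mean()], start_scale * np.array([1.0, -1.0]), [0.0]]
            )
            res = minimize(
                lambda t: -_marginal_objective(t, y, W, Z, prior),
                theta0,
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 40_000},
            )
            if best is None or res.fun < best.fun:
                best = res
        assert fit.alpha[0] == pytest.approx(best.x[0], abs=1e-4)
        assert fit.gamma == pytest.approx(best.x[1:3], abs=1e-4)
        assert fit.sigma2 == pytest.approx(np.exp(best.x[3]), abs=1e-4)

    def test_shrinkage_monotone_in_prior(self):
        """On a one-marker instance the fixed point shrinks monotonically:
        a larger prior scale S means a larger working marker variance
        (sigma_k^2 = (gamma^2 + S)/(nu + 1)), i.e. weaker shrinkage, so
        max|gamma| is non-decreasing in S; more prior degrees of freedom nu
        mean stronger shrinkage, so max|gamma| is non-increasing in nu."""
        rng = np.random.default_rng(3)
        n = 30
        W = np.ones((n, 1))
        Z = rng.integers(0, 3, (n, 1)).astype(float)
        y = 1.0 + Z[:, 0] * 0.8 + 0.5 * rng.standard_normal(n)

        def top(**kw):
            fit = fit_embayesa(
                WhitenedData(y, W, Z), PriorConfig(tol=1e-10, max_iter=5000, **kw)
            )
            return np.max(np.abs(fit.gamma))

        by_scale = [top(scale=s) for s in (1e-4, 1e-2, 1.0, 100.0)]
        assert all(a <= b + 1e-8 for a, b in zip(by_scale, by_scale[1:]))
        by_nu = [top(nu=v) for v in (1.0, 2.0, 4.0, 16.0, 64.0)]
        assert all(a >= b - 1e-8 for a, b in zip(by_nu, by_nu[1:]))

    def test_iteration_cap_respected(self):
        rng = np.random.default_rng(5)
        n, q = 40, 100
        Z = rng.integers(0, 3, (n, q)).astype(float)
        y = rng.standard_normal(n)
        fit = fit_embayesa(WhitenedData(y, np.ones((n, 1)), Z), PriorConfig(max_iter=3))
        assert fit.n_iter <= 3


class TestFitEmbai:
    def test_zero_lambda_reduces_to_emba_exactly(self, small_dataset):
        ds, K = small_dataset
        y, W = ds.phenotype, np.ones((K.n, 1))
        a = fit_embai(y, W, ds.genotypes, K, lambda_g=0.0)
        b = fit_emba(y, W, ds.genotypes)
        assert np.array_equal(a.gamma, b.gamma)
        assert a.sigma2 == b.sigma2
        assert a.n_iter == b.n_iter

    def test_bit_stable_across_runs(self):
        g = simulate_genotypes(40, 120, seed=21)
        K = compute_grm(g)
        scen = make_scenario_one_qtn(g, background_multiplier=2.0, seed=22)
        ds = simulate_phenotype(g, scen, K)
        W = np.ones((40, 1))
        a = fit_embai(ds.phenotype, W, g, K)
        b = fit_embai(ds.phenotype, W, g, K)
        assert np.array_equal(a.gamma, b.gamma)
        assert a.lambda_g == b.lambda_g

    def test_records_lambda_and_tag(self, small_dataset):
        ds, K = small_dataset
        fit = fit_embai(ds.phenotype, np.ones((K.n, 1)), ds.genotypes, K)
        assert fit.method_tag == "emBAI"
        assert fit.lambda_g is not None and fit.lambda_g >= 0
        assert_ascent(fit.log_posterior_trace)


class TestPredictGebv:
    def test_zero_effects_zero_gebv(self, small_dataset):
        ds, K = small_dataset
        fit = fit_emba(ds.phenotype, np.ones((K.n, 1)), ds.genotypes,
                       PriorConfig(max_iter=1))
        zeroed = type(fit)(
            alpha=fit.alpha, gamma=np.zeros_like(fit.gamma), sigma_k2=fit.sigma_k2,
            sigma2=fit.sigma2, n_iter=1, converged=True,
            log_posterior_trace=fit.log_posterior_trace, method_tag="emBA",
        )
        pred = predict_gebv(zeroed, ds.genotypes)
        assert np.all(pred.gebv == 0.0)

    def test_single_marker_scaling(self):
        from embai.em_core import EMFit

        fit = EMFit(
            alpha=np.array([0.0]), gamma=np.array([0.5]), sigma_k2=np.array([1.0]),
            sigma2=1.0, n_iter=1, converged=True,
            log_posterior_trace=np.array([0.0]), method_tag="emBA",
        )
        Z = np.array([[0.0], [1.0], [2.0]])
        pred = predict_gebv(fit, Z)
        assert pred.gebv == pytest.approx([0.0, 0.5, 1.0])

    def test_gebv_tracks_genetic_signal(self):
        """On a many-QTN architecture the GEBV correlates more with the true
        genetic values than with the residual noise."""
        from embai import make_scenario_multi_qtn

        g = simulate_genotypes(300, 600, seed=77)
        K = compute_grm(g)
        scen = make_scenario_multi_qtn(g, background_multiplier=2.0, seed=78)
        ds = simulate_phenotype(g, scen, K)
        fit = fit_embai(ds.phenotype, np.ones((300, 1)), g, K)
        pred = predict_gebv(fit, g)
        r_gen = np.corrcoef(pred.gebv, ds.genetic)[0, 1]
        r_noise = np.corrcoef(pred.gebv, ds.residual)[0, 1]
        assert r_gen > r_noise
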